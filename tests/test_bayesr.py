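import numpy as np
import pytest

from boamap import (
    BayesR,
    BayesRConfig,
    FixedEffectsSpec,
    mcmc_diagnostics,
    pip_inclusion,
    predict_gebv,
)


def quick_cfg(**kw):
    base = dict(n_iter=3000, burn_in=1000, thin=2)
    base.update(kw)
    return BayesRConfig(**base)


class TestConfigValidation:
    def test_defaults_match_model(self):
        cfg = BayesRConfig()
        assert cfg.variance_multipliers == (0.0, 1e-4, 1e-3, 1e-2)
        assert cfg.dirichlet_alpha == (1.0, 1.0, 1.0, 1.0)
        assert cfg.n_iter == 50_000 and cfg.burn_in == 20_000

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_iter=100, burn_in=100),
            dict(variance_multipliers=(1e-4, 1e-3)),
            dict(variance_multipliers=(0.0, 1e-3, 1e-4, 1e-2)),
            dict(dirichlet_alpha=(1.0, 1.0)),
            dict(h2_init=1.5),
            dict(sigma_g_mode="bogus"),
            dict(pr_init=(0.5, 0.5, 0.5, 0.5)),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            BayesRConfig(**kw)


class TestPipInclusion:
    @pytest.mark.parametrize(
        "pips,expected",
        [((0.9, 0.05, 0.03, 0.02), 0.10), ((1, 0, 0, 0), 0.0), ((0, 0, 0, 1), 1.0)],
    )
    def test_values(self, pips, expected):
        assert pip_inclusion(np.array(pips)) == pytest.approx(expected)

    def test_matrix_form(self):
        p = np.array([[0.9, 0.1, 0.0, 0.0], [0.2, 0.3, 0.3, 0.2]])
        assert np.allclose(pip_inclusion(p), [0.1, 0.8])


class TestPredictGebv:
    def test_zero_effects_zero_gebv(self):
        X = np.ones((3, 4))
        assert np.array_equal(predict_gebv(X, np.zeros(4)), np.zeros(3))

    def test_single_effect_dosage_two(self):
        X = np.zeros((1, 5))
        X[0, 2] = 2.0
        g = np.zeros(5)
        g[2] = 0.7
        assert predict_gebv(X, g)[0] == pytest.approx(1.4)

    def test_matches_double_loop_on_fixture(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (5, 9)).astype(float)
        g = rng.normal(size=9)
        naive = np.array([sum(X[i, j] * g[j] for j in range(9)) for i in range(5)])
        assert np.allclose(predict_gebv(X, g), naive)
        import scipy.sparse as sp

        assert np.allclose(predict_gebv(sp.csc_matrix(X), g), naive)

    def test_misaligned_columns_rejected(self):
        with pytest.raises(ValueError):
            predict_gebv(np.ones((2, 3)), np.ones(4))


class TestGibbsSampler:
    def test_no_signal_all_zero_columns(self):
        # with completely uninformative columns the class indicator follows
        # the mixture proportions, whose posterior mean stays near the
        # Dirichlet(1,1,1,1) prior mean, so PIP_inclusion ~ 0.75
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.0, 120)
        X = np.zeros((120, 30))
        res = BayesR(y, X, config=quick_cfg(n_iter=6000, burn_in=2000)).fit(seed=5)
        assert res.fixed_effects_["intercept"] == pytest.approx(y.mean(), abs=0.3)
        assert res.pip_inclusion.mean() == pytest.approx(0.75, abs=0.15)

    def test_conjugate_ridge_value(self):
        # one column, classes {0, 0.01}, both variances fixed: posterior
        # mean given inclusion is the closed-form ridge estimate
        rng = np.random.default_rng(5)
        n = 150
        x = rng.integers(0, 3, n).astype(float)
        x -= x.mean()
        y = 0.25 * x + rng.normal(0, 1, n)
        y -= y.mean()
        se, sg = 1.0, 4.0
        cfg = BayesRConfig(
            variance_multipliers=(0.0, 1e-2),
            dirichlet_alpha=(1e-9, 1e9),  # pins Pr on the nonzero class
            n_iter=12000,
            burn_in=2000,
            thin=1,
            sigma_g_mode="fixed",
            sigma_e_mode="fixed",
            sigma_g_init=sg,
            sigma_e_init=se,
        )
        res = BayesR(y, x.reshape(-1, 1), config=cfg).fit(seed=11)
        c = x @ x + se / (0.01 * sg)
        ridge = (x @ y) / c
        mc_se = np.sqrt(se / c) / np.sqrt(res.n_kept / 10)  # conservative ESS
        assert abs(res.effects_[0] - ridge) < 3 * mc_se
        assert res.pip_inclusion[0] == pytest.approx(1.0)

    def test_blup_limit_on_small_instance(self):
        # single nonzero class, Pr pinned, variances fixed: posterior mean
        # effects converge to the multivariate ridge (BLUP) solution
        rng = np.random.default_rng(9)
        n, m = 200, 8
        X = rng.normal(size=(n, m))
        X -= X.mean(axis=0)
        beta = rng.normal(0, 0.3, m)
        y = X @ beta + rng.normal(0, 1, n)
        y -= y.mean()
        se, sg = 1.0, 10.0
        lam = se / (0.01 * sg)
        blup = np.linalg.solve(X.T @ X + lam * np.eye(m), X.T @ y)
        cfg = BayesRConfig(
            variance_multipliers=(0.0, 1e-2),
            dirichlet_alpha=(1e-9, 1e9),
            n_iter=15000,
            burn_in=3000,
            thin=1,
            sigma_g_mode="fixed",
            sigma_e_mode="fixed",
            sigma_g_init=sg,
            sigma_e_init=se,
        )
        res = BayesR(y, X, config=cfg).fit(seed=3)
        assert np.allclose(res.effects_, blup, atol=0.12)

    def test_signal_recovery_small(self):
        rng = np.random.default_rng(12)
        n, m = 300, 60
        X = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        true = [7, 31]
        y = 0.6 * X[:, 7] - 0.5 * X[:, 31] + rng.normal(0, 0.8, n)
        res = BayesR(y, X, config=quick_cfg(center=True, h2_init=0.4)).fit(seed=2)
        assert all(res.pip_inclusion[j] > 0.9 for j in true)
        null = np.setdiff1d(np.arange(m), true)
        assert res.pip_inclusion[null].mean() < res.pip_inclusion[true].mean()
        # effect signs recovered
        assert res.effects_[7] > 0.3 and res.effects_[31] < -0.2

    def test_pr_on_simplex_and_counts_conserved(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        X = rng.binomial(2, 0.5, (100, 20)).astype(float)
        res = BayesR(y, X, config=quick_cfg()).fit(seed=8)
        assert np.allclose(res.traces["pr"].sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.traces["pr"] >= 0)
        assert np.allclose(res.pip.sum(axis=1), 1.0, atol=1e-9)
        assert res.mean_class_counts_.sum() == pytest.approx(20.0)
        assert np.all(res.traces["sigma_e"] > 0)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=80)
        X = rng.binomial(2, 0.3, (80, 15)).astype(float)
        r1 = BayesR(y, X, config=quick_cfg()).fit(seed=77)
        r2 = BayesR(y, X, config=quick_cfg()).fit(seed=77)
        for key in ("fixed", "sigma_e", "sigma_g", "pr"):
            assert np.array_equal(r1.traces[key], r2.traces[key])
        assert np.array_equal(r1.effects_, r2.effects_)
        assert np.array_equal(r1.pip, r2.pip)
        r3 = BayesR(y, X, config=quick_cfg()).fit(seed=78)
        assert not np.array_equal(r1.traces["sigma_e"], r3.traces["sigma_e"])

    def test_variance_recovery(self):
        # posterior sigma_g^2 + sigma_e^2 ~ var(y) on simulated data
        rng = np.random.default_rng(31)
        n, m = 400, 100
        X = rng.binomial(2, 0.5, (n, m)).astype(float)
        beta = np.zeros(m)
        beta[rng.choice(m, 5, replace=False)] = rng.normal(0, 0.3, 5)
        g = X @ beta
        y = g + rng.normal(0, 1.0, n)
        res = BayesR(y, X, config=quick_cfg(n_iter=5000, burn_in=2000, center=True)).fit(seed=6)
        assert res.sigma_e_ == pytest.approx(1.0, rel=0.25)

    def test_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            BayesR(np.array([1.0, np.nan]), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="align"):
            BayesR(np.zeros(3), np.zeros((2, 1)))
        model = BayesR(np.zeros(3), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="seed"):
            model.fit()


class TestFixedEffects:
    def test_reference_level_coding_full_rank(self):
        import pandas as pd

        df = pd.DataFrame(
            {"cg": ["a", "a", "b", "b", "c"], "age": [1.0, 2, 3, 4, 5]}
        )
        W, names = FixedEffectsSpec().design(df)
        assert W.shape == (5, 4)  # intercept + 2 cg dummies + age
        assert names == ["intercept", "cg[b]", "cg[c]", "age"]
        assert np.linalg.matrix_rank(W) == 4

    def test_rank_deficiency_detected(self):
        import pandas as pd

        df = pd.DataFrame({"cg": ["a", "a"], "dup": [1.0, 1.0], "age": [1.0, 1.0]})
        with pytest.raises(ValueError, match="rank"):
            FixedEffectsSpec(factors=(), covariates=("dup", "age")).design(df)


class TestDiagnostics:
    def test_split_half_agreement_on_signal(self):
        rng = np.random.default_rng(14)
        n, m = 250, 40
        X = rng.binomial(2, 0.4, (n, m)).astype(float)
        y = 0.8 * X[:, 3] + rng.normal(0, 0.8, n)
        res = BayesR(y, X, config=quick_cfg(n_iter=6000, burn_in=2000, center=True)).fit(seed=4)
        d = mcmc_diagnostics(res)
        assert d["split_half_pip_correlation"] > 0.9
        assert d["sigma_e_mean"] > 0 and d["n_kept"] == res.n_kept

    def test_summary_prints_key_quantities(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=60)
        X = rng.binomial(2, 0.5, (60, 10)).astype(float)
        res = BayesR(y, X, config=quick_cfg()).fit(seed=1)
        text = res.summary()
        assert "sigma_e^2" in text and "mixture proportions" in text
        assert str(res.model.Xcsc.shape[1]) in text
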