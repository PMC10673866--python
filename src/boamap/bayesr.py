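"""BayesR: four-class normal-mixture Bayesian regression by Gibbs sampling.

The model for a trait vector y is

    y = 1 mu + (fixed effects) + X g + e,

where each column effect g_i belongs to one of four normal components with
variances {0, 0.0001, 0.001, 0.01} x sigma_g^2; component proportions Pr
carry a Dirichlet(1,1,1,1) prior. Sampling is single-site Gibbs: fixed
effects from their normal full conditionals (flat priors), each SNP class
indicator from its effect-integrated (collapsed) conditional followed by
the effect's normal full conditional, Pr from Dirichlet(alpha + counts),
and the variance components from scaled-inverse-chi-square conditionals.
Posterior summaries (effect means, class-membership PIPs, GEBV = X ghat)
average the post-burn-in thinned samples.

The API follows the statsmodels convention: construct a :class:`BayesR`
model from data, call :meth:`BayesR.fit`, and read estimates off the
returned :class:`BayesRResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit


@dataclass(frozen=True)
class BayesRConfig:
    """Sampler settings.

    variance_multipliers must start at exactly 0 and increase; they scale
    the genetic variance sigma_g^2 into the per-class effect variances.
    ``sigma_g_mode`` "sampled" updates sigma_g^2 from the nonzero effects'
    scaled-inverse-chi-square full conditional; "fixed" pins it at
    ``h2_init * var(y)``; "empirical" pins it at an empirical-Bayes value
    calibrated from a marginal association screen: sigma_g^2 =
    median(beta_hat^2 over screen hits) / max multiplier, so the largest
    mixture class accommodates effects of the size the data show (falls
    back to the "fixed" value when the screen finds nothing). The
    calibration matters for sparse architectures, where the conjugate
    sigma_g^2 update can deflate once weakly informative columns crowd the
    smallest nonzero class. The residual prior is scaled-inverse-chi-square
    (df, scale); the (-2, 0) default is flat.
    """

    variance_multipliers: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    dirichlet_alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int | None = None
    sigma_g_mode: str = "sampled"
    sigma_e_mode: str = "sampled"
    h2_init: float = 0.20
    residual_prior: tuple[float, float] = (-2.0, 0.0)
    genetic_prior_df: float = 4.0
    sigma_g_init: float | None = None  # overrides h2_init * var(y)
    sigma_e_init: float | None = None  # overrides (1 - h2_init) * var(y)
    center: bool = False  # centre design columns inside the sampler
    #: initial mixture proportions; None starts at the prior mean (uniform).
    #: A sparse start such as (0.997, 0.001, 0.001, 0.001) makes the chain
    #: grow the model from the data instead of pruning a saturated start,
    #: the usual warm start for variable-selection samplers.
    pr_init: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        m = self.variance_multipliers
        if m[0] != 0.0 or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("multipliers must start at 0 and increase")
        if len(self.dirichlet_alpha) != len(m):
            raise ValueError("alpha length must match the multipliers")
        if not 0.0 < self.h2_init < 1.0:
            raise ValueError("h2_init must lie in (0, 1)")
        if self.sigma_g_mode not in ("fixed", "sampled", "empirical"):
            raise ValueError("sigma_g_mode must be 'fixed', 'sampled' or 'empirical'")
        if self.sigma_e_mode not in ("fixed", "sampled"):
            raise ValueError("sigma_e_mode must be 'fixed' or 'sampled'")
        if self.pr_init is not None:
            if len(self.pr_init) != len(m) or abs(sum(self.pr_init) - 1.0) > 1e-9:
                raise ValueError("pr_init must be a length-K probability vector")


@dataclass
class FixedEffectsSpec:
    """Fixed part of the model: intercept, factor terms, covariates."""

    intercept: bool = True
    factors: tuple[str, ...] = ("cg",)
    covariates: tuple[str, ...] = ("age",)

    def design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Build the dense fixed-effect design with reference-level coding."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        n = len(data)
        if self.intercept:
            cols.append(np.ones(n))
            names.append("intercept")
        for f in self.factors:
            levels = pd.unique(data[f])
            for lev in levels[1:]:  # first level is the reference
                cols.append((data[f] == lev).to_numpy(dtype=float))
                names.append(f"{f}[{lev}]")
        for c in self.covariates:
            v = data[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite covariate {c!r}")
            cols.append(v)
            names.append(c)
        W = np.column_stack(cols) if cols else np.empty((n, 0))
        if W.shape[1] and np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("rank-deficient fixed-effect design")
        return W, names


@njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.gamma(df / 2.0, 1.0)


@njit(cache=True)
def _run_chain(
    y,
    W,
    wtw,
    indptr,
    indices,
    data,
    xtx,
    mu,
    colsum,
    gammas,
    alpha,
    pr0,
    n_iter,
    burn_in,
    thin,
    seed,
    sigma_g_sampled,
    sigma_e_sampled,
    sigma_g0,
    sigma_e0,
    df_e,
    scale_e,
    df_g,
    scale_g,
):  # pragma: no cover - exercised through BayesR.fit
    np.random.seed(seed)
    n = y.shape[0]
    p = W.shape[1]
    ncol = xtx.shape[0]
    K = gammas.shape[0]

    beta = np.zeros(p)
    g = np.zeros(ncol)
    cls = np.zeros(ncol, dtype=np.int64)
    # stored residual r plus a scalar offset c: the true residual is r - c,
    # which lets centred columns (x - mu) update r sparsely
    r = y.copy()
    c_off = 0.0
    rsum = 0.0
    for i in range(n):
        rsum += r[i]
    wsum = np.zeros(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, l]
        wsum[l] = s
    sigma_e = sigma_e0
    sigma_g = sigma_g0
    pr = pr0.copy()

    n_keep = (n_iter - burn_in + thin - 1) // thin
    beta_trace = np.zeros((n_keep, p))
    se_trace = np.zeros(n_keep)
    sg_trace = np.zeros(n_keep)
    pr_trace = np.zeros((n_keep, K))
    g_sum = np.zeros(ncol)
    g_sq_sum = np.zeros(ncol)
    pip_counts = np.zeros((ncol, K), dtype=np.int64)
    pip_counts_a = np.zeros((ncol, K), dtype=np.int64)  # first half of kept draws
    logp = np.zeros(K)
    kept = 0

    for it in range(n_iter):
        # (a) fixed effects: normal full conditionals, flat priors
        for l in range(p):
            rhs = -c_off * wsum[l]
            for i in range(n):
                rhs += W[i, l] * r[i]
            rhs += wtw[l] * beta[l]
            mean = rhs / wtw[l]
            new = mean + np.sqrt(sigma_e / wtw[l]) * np.random.standard_normal()
            diff = beta[l] - new
            for i in range(n):
                r[i] += W[i, l] * diff
            rsum += wsum[l] * diff
            beta[l] = new

        # (b) SNP effects: collapsed class indicator, then the effect
        counts = np.zeros(K, dtype=np.int64)
        for j in range(ncol):
            a0, a1 = indptr[j], indptr[j + 1]
            rhs = 0.0
            for t in range(a0, a1):
                rhs += data[t] * r[indices[t]]
            rhs += -colsum[j] * c_off - mu[j] * (rsum - n * c_off)
            rhs += xtx[j] * g[j]
            logp[0] = np.log(pr[0])
            best = logp[0]
            for k in range(1, K):
                v = gammas[k] * sigma_g
                denom = xtx[j] * v + sigma_e
                logp[k] = (
                    np.log(pr[k])
                    + 0.5 * np.log(sigma_e / denom)
                    + 0.5 * rhs * rhs * v / (sigma_e * denom)
                )
                if logp[k] > best:
                    best = logp[k]
            tot = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - best)
                tot += logp[k]
            u = np.random.random() * tot
            k_new = K - 1
            acc = 0.0
            for k in range(K):
                acc += logp[k]
                if u <= acc:
                    k_new = k
                    break
            g_old = g[j]
            if k_new == 0:
                g_new = 0.0
            else:
                v = gammas[k_new] * sigma_g
                c = xtx[j] + sigma_e / v
                g_new = rhs / c + np.sqrt(sigma_e / c) * np.random.standard_normal()
            if g_old != g_new:
                diff = g_old - g_new
                for t in range(a0, a1):
                    r[indices[t]] += data[t] * diff
                rsum += colsum[j] * diff
                c_off += mu[j] * diff
            g[j] = g_new
            cls[j] = k_new
            counts[k_new] += 1

        # (c) mixture proportions ~ Dirichlet(alpha + counts)
        tot = 0.0
        for k in range(K):
            pr[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
            tot += pr[k]
        for k in range(K):
            pr[k] /= tot

        # (d) residual variance ~ scaled-inverse-chi-square
        if sigma_e_sampled:
            rss = 0.0
            for i in range(n):
                rss += (r[i] - c_off) * (r[i] - c_off)
            sigma_e = (rss + df_e * scale_e) / _chi2(n + df_e)

        # (e) genetic variance from the nonzero effects
        if sigma_g_sampled:
            ssq = 0.0
            nnz = 0
            for j in range(ncol):
                if cls[j] > 0:
                    ssq += g[j] * g[j] / gammas[cls[j]]
                    nnz += 1
            sigma_g = (ssq + df_g * scale_g) / _chi2(nnz + df_g)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for l in range(p):
                beta_trace[kept, l] = beta[l]
            se_trace[kept] = sigma_e
            sg_trace[kept] = sigma_g
            for k in range(K):
                pr_trace[kept, k] = pr[k]
            for j in range(ncol):
                g_sum[j] += g[j]
                g_sq_sum[j] += g[j] * g[j]
                pip_counts[j, cls[j]] += 1
                if kept < n_keep // 2:
                    pip_counts_a[j, cls[j]] += 1
            kept += 1

    return (
        beta_trace,
        se_trace,
        sg_trace,
        pr_trace,
        g_sum,
        g_sq_sum,
        pip_counts,
        pip_counts_a,
    )


class BayesR:
    """BayesR mixture model for a trait on a (possibly origin-partitioned)
    SNP design matrix.

    Parameters
    ----------
    y : 1-D trait vector, complete (no NaN).
    X : (n, ncol) SNP design matrix, dense or scipy sparse; raw dosages.
    fixed_data : optional data frame holding the fixed-effect columns.
    fixed : FixedEffectsSpec describing intercept/factors/covariates; with
        no ``fixed_data`` only an intercept is fitted.
    config : BayesRConfig.
    column_labels : optional data frame (snp_id, class) aligned with X's
        columns, carried through to effect tables.
    """

    def __init__(
        self,
        y,
        X,
        fixed_data: pd.DataFrame | None = None,
        fixed: FixedEffectsSpec | None = None,
        config: BayesRConfig | None = None,
        column_labels: pd.DataFrame | None = None,
    ):
        self.y = np.asarray(y, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trait values")
        self.Xcsc = sp.csc_matrix(X, dtype=np.float64)
        if self.Xcsc.shape[0] != self.y.shape[0]:
            raise ValueError("X rows do not align with y")
        self.config = config or BayesRConfig()
        if fixed_data is not None:
            spec = fixed or FixedEffectsSpec()
            self.W, self.fixed_names = spec.design(fixed_data)
            if not spec.intercept:
                raise ValueError("model requires an intercept")
        else:
            self.W = np.ones((self.y.shape[0], 1))
            self.fixed_names = ["intercept"]
        self.column_labels = column_labels

    @classmethod
    def from_dataframe(
        cls,
        pheno: pd.DataFrame,
        X,
        trait: str = "trait",
        fixed: FixedEffectsSpec | None = None,
        **kwargs,
    ) -> "BayesR":
        """Build from a phenotype frame whose rows align with X's rows."""
        return cls(pheno[trait].to_numpy(), X, fixed_data=pheno, fixed=fixed, **kwargs)

    def fit(self, seed: int | None = None) -> "BayesRResults":
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if seed is None:
            raise ValueError("a seed is required (config.seed or fit(seed=...))")
        gammas = np.asarray(cfg.variance_multipliers, dtype=np.float64)
        alpha = np.asarray(cfg.dirichlet_alpha, dtype=np.float64)
        n = self.y.shape[0]
        colsum = np.asarray(self.Xcsc.sum(axis=0)).ravel()
        xtx = np.asarray(self.Xcsc.multiply(self.Xcsc).sum(axis=0)).ravel()
        if cfg.center:
            mu = colsum / n
            xtx = xtx - n * mu**2
        else:
            mu = np.zeros_like(colsum)
        self.column_means_ = mu
        wtw = (self.W**2).sum(axis=0)
        vary = float(np.var(self.y))
        sigma_g0 = cfg.sigma_g_init
        if sigma_g0 is None:
            sigma_g0 = cfg.h2_init * vary if vary > 0 else 1.0
            if cfg.sigma_g_mode == "empirical":
                cal = self._marginal_screen_sigma_g(xtx, mu)
                if cal is not None:
                    sigma_g0 = cal
        sigma_e0 = cfg.sigma_e_init
        if sigma_e0 is None:
            sigma_e0 = (1.0 - cfg.h2_init) * vary if vary > 0 else 1.0
        df_g = cfg.genetic_prior_df
        # prior mean of sigma_g^2 set at h2_init * var(y)
        scale_g = sigma_g0 * (df_g - 2.0) / df_g if df_g > 2 else sigma_g0
        out = _run_chain(
            self.y,
            self.W,
            wtw,
            self.Xcsc.indptr.astype(np.int64),
            self.Xcsc.indices.astype(np.int64),
            self.Xcsc.data,
            xtx,
            mu,
            colsum,
            gammas,
            alpha,
            (
                np.asarray(cfg.pr_init, dtype=np.float64)
                if cfg.pr_init is not None
                else np.full(len(gammas), 1.0 / len(gammas))
            ),
            cfg.n_iter,
            cfg.burn_in,
            cfg.thin,
            int(seed) % (2**31 - 1),
            cfg.sigma_g_mode == "sampled",  # "fixed"/"empirical" pin sigma_g
            cfg.sigma_e_mode == "sampled",
            sigma_g0,
            sigma_e0,
            float(cfg.residual_prior[0]),
            float(cfg.residual_prior[1]),
            df_g,
            scale_g,
        )
        return BayesRResults(self, seed, *out)

    def _marginal_screen_sigma_g(self, xtx: np.ndarray, mu: np.ndarray) -> float | None:
        """Empirical-Bayes sigma_g^2 from a single-column association screen.

        Residualise y on the fixed effects, compute each column's marginal
        OLS effect and z-statistic, and take the median beta_hat^2 over
        columns passing a Bonferroni-style 2*ln(ncol) z^2 cut (median, so
        low-dosage columns with wild estimates cannot dominate); dividing
        by the top multiplier gives the genetic variance at which the
        largest mixture class matches the observed effect sizes.
        """
        beta, *_ = np.linalg.lstsq(self.W, self.y, rcond=None)
        y_adj = self.y - self.W @ beta
        rhs = np.asarray(self.Xcsc.T @ y_adj).ravel() - mu * y_adj.sum()
        ok = xtx > 0
        s2 = float(np.var(y_adj))
        z2 = np.zeros_like(rhs)
        z2[ok] = rhs[ok] ** 2 / (xtx[ok] * s2)
        cut = 2.0 * np.log(max(self.Xcsc.shape[1], 2))
        hits = ok & (z2 > cut)
        if not hits.any():
            return None
        beta2 = (rhs[hits] / xtx[hits]) ** 2
        top = max(self.config.variance_multipliers)
        return float(np.median(beta2) / top)


class BayesRResults:
    """Posterior summaries of a fitted BayesR model.

    Attributes
    ----------
    effects_ : posterior mean effect per design column (ghat).
    effects_sd_ : posterior standard deviation per column.
    pip : (ncol, K) class-membership posterior probabilities (rows sum to 1).
    pip_inclusion : per-column probability of a nonzero effect (1 - PIP_1).
    fixed_effects_ : posterior means of the fixed effects.
    sigma_e_, sigma_g_, pr_ : posterior means of the variance components
        and mixture proportions.
    traces : dict of retained post-burn-in thinned draws.
    """

    def __init__(
        self,
        model: BayesR,
        seed: int,
        beta_trace,
        se_trace,
        sg_trace,
        pr_trace,
        g_sum,
        g_sq_sum,
        pip_counts,
        pip_counts_a,
    ):
        self.model = model
        self.seed = seed
        self.n_kept = len(se_trace)
        self.traces = {
            "fixed": beta_trace,
            "sigma_e": se_trace,
            "sigma_g": sg_trace,
            "pr": pr_trace,
        }
        self.effects_ = g_sum / self.n_kept
        var = np.maximum(g_sq_sum / self.n_kept - self.effects_**2, 0.0)
        self.effects_sd_ = np.sqrt(var)
        self.pip = pip_counts / self.n_kept
        self._pip_counts = pip_counts
        self._pip_counts_a = pip_counts_a
        self.pip_inclusion = 1.0 - self.pip[:, 0]
        self.fixed_effects_ = pd.Series(beta_trace.mean(axis=0), index=model.fixed_names)
        self.sigma_e_ = float(se_trace.mean())
        self.sigma_g_ = float(sg_trace.mean())
        self.pr_ = pr_trace.mean(axis=0)
        self.mean_class_counts_ = self.pip.sum(axis=0)

    def predict(self, X=None) -> np.ndarray:
        """GEBV = X ghat (training-matrix GEBV when X is omitted).

        With a centred fit the training column means are subtracted, a
        constant shift of the whole GEBV vector per column.
        """
        if X is None:
            X = self.model.Xcsc
        gebv = predict_gebv(X, self.effects_)
        mu = getattr(self.model, "column_means_", None)
        if mu is not None and np.any(mu):
            gebv = gebv - float(mu @ self.effects_)
        return gebv

    def effects_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "effect_mean": self.effects_,
                "effect_sd": self.effects_sd_,
            }
        )
        for k in range(self.pip.shape[1]):
            df[f"PIP_{k + 1}"] = self.pip[:, k]
        df["PIP_inclusion"] = self.pip_inclusion
        if self.model.column_labels is not None:
            df = pd.concat(
                [self.model.column_labels.reset_index(drop=True), df], axis=1
            )
        return df

    def split_half_pip(self) -> tuple[np.ndarray, np.ndarray]:
        """Inclusion PIPs from the first and second half of kept draws."""
        half = self.n_kept // 2
        a = self._pip_counts_a
        b = self._pip_counts - a
        return 1.0 - a[:, 0] / half, 1.0 - b[:, 0] / (self.n_kept - half)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "BayesR mixture model — Gibbs sampler results",
            "=" * 52,
            f"observations:        {self.model.y.shape[0]}",
            f"design columns:      {self.model.Xcsc.shape[1]}",
            f"iterations:          {cfg.n_iter} (burn-in {cfg.burn_in}, thin {cfg.thin})",
            f"retained draws:      {self.n_kept}",
            f"seed:                {self.seed}",
            "",
            "posterior means",
            "-" * 52,
            f"sigma_e^2 (residual):  {self.sigma_e_:.6g}",
            f"sigma_g^2 (genetic):   {self.sigma_g_:.6g}",
            "mixture proportions Pr: "
            + ", ".join(f"{p:.4f}" for p in self.pr_),
            "mean class counts:      "
            + ", ".join(f"{c:.1f}" for c in self.mean_class_counts_),
            "",
            "fixed effects",
            "-" * 52,
        ]
        for name, val in self.fixed_effects_.items():
            lines.append(f"{name:<22s} {val: .6g}")
        k = min(5, len(self.effects_))
        top = np.argsort(self.pip_inclusion)[::-1][:k]
        lines += ["", f"top {k} columns by PIP_inclusion", "-" * 52]
        for j in top:
            lines.append(
                f"col {j:<6d} effect {self.effects_[j]: .5g}  "
                f"PIP {self.pip_inclusion[j]:.3f}"
            )
        return "\n".join(lines)


def gibbs_sample(
    y,
    fixed_data: pd.DataFrame | None,
    X,
    cfg: BayesRConfig,
    fixed: FixedEffectsSpec | None = None,
    column_labels: pd.DataFrame | None = None,
    seed: int | None = None,
) -> BayesRResults:
    """Functional wrapper: build a :class:`BayesR` model and fit it."""
    model = BayesR(
        y, X, fixed_data=fixed_data, fixed=fixed, config=cfg, column_labels=column_labels
    )
    return model.fit(seed=seed)


def pip_inclusion(pips: np.ndarray) -> np.ndarray | float:
    """Probability of a nonzero effect: PIP_2 + PIP_3 + PIP_4 = 1 - PIP_1."""
    p = np.asarray(pips, dtype=float)
    if p.ndim == 1:
        return float(p[1:].sum())
    return p[:, 1:].sum(axis=1)


def predict_gebv(X, g_hat: np.ndarray) -> np.ndarray:
    """Genomic breeding values GEBV = X ghat."""
    g_hat = np.asarray(g_hat, dtype=float)
    if X.shape[1] != g_hat.shape[0]:
        raise ValueError("effect vector does not align with the design columns")
    if sp.issparse(X):
        return np.asarray(X @ g_hat).ravel()
    return np.asarray(X, dtype=float) @ g_hat


def mcmc_diagnostics(res: BayesRResults) -> dict:
    """Trace means plus split-half agreement of the inclusion PIPs."""
    a, b = res.split_half_pip()
    if np.std(a) > 0 and np.std(b) > 0:
        corr = float(np.corrcoef(a, b)[0, 1])
    else:
        corr = 1.0 if np.allclose(a, b) else 0.0
    return {
        "sigma_e_mean": res.sigma_e_,
        "sigma_g_mean": res.sigma_g_,
        "pr_mean": res.pr_.tolist(),
        "fixed_means": res.fixed_effects_.to_dict(),
        "split_half_pip_correlation": corr,
        "n_kept": res.n_kept,
    }
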