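"""Cross-validated genomic prediction and QTL-mapping reports.

Accuracy is the Pearson correlation between GEBV and the phenotype
adjusted for contemporary group and age, divided by sqrt(h2) (h2 = 0.20
for the reproductive maturity score the method was developed on); bias is
the regression slope of GEBV on adjusted phenotype (the conventional
dispersion slope, phenotype on GEBV, is also reported). Folds are a
uniform random k-way split, persisted so every analysis scores the same
validation groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesr import BayesR, BayesRConfig, BayesRResults, FixedEffectsSpec, predict_gebv
from .design import build_control_xmatrix, build_origin_xmatrix
from .io import PhasedGenotypes, PhenotypeTable, write_tsv
from .origin import OriginCalls
from .windows import WindowSet


def adjust_phenotypes(ph: PhenotypeTable) -> pd.Series:
    """OLS residuals of trait on intercept + cg factors + age covariate."""
    df = ph.with_trait()
    sizes = df.groupby("cg", observed=True)["animal_id"].count()
    singletons = sizes[sizes == 1]
    if len(singletons):
        warnings.warn(
            f"{len(singletons)} singleton contemporary group(s); their residuals are 0",
            stacklevel=2,
        )
    W, _ = FixedEffectsSpec(factors=("cg",), covariates=("age",)).design(df)
    y = df["trait"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ beta
    return pd.Series(resid, index=df["animal_id"].tolist(), name="y_adj")


@dataclass
class FoldPlan:
    """Deterministic k-fold partition of the animals."""

    k: int
    seed: int
    assignment: pd.Series  # animal_id -> fold in [0, k)

    def validation_ids(self, fold: int) -> list[str]:
        return self.assignment.index[self.assignment == fold].tolist()

    def training_ids(self, fold: int) -> list[str]:
        return self.assignment.index[self.assignment != fold].tolist()

    def to_tsv(self, path: str) -> None:
        df = self.assignment.rename("fold").rename_axis("animal_id").reset_index()
        df.insert(0, "k", self.k)
        df.insert(1, "seed", self.seed)
        write_tsv(df, path)

    @classmethod
    def from_tsv(cls, path: str) -> "FoldPlan":
        from .io import read_tsv

        df = read_tsv(path)
        s = pd.Series(df["fold"].to_numpy(), index=df["animal_id"].astype(str).tolist())
        return cls(k=int(df["k"].iloc[0]), seed=int(df["seed"].iloc[0]), assignment=s)


def make_folds(animal_ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Random folds of near-equal size (differing by at most one animal)."""
    rng = np.random.default_rng(seed)
    n = len(animal_ids)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[order] = np.arange(n) % k
    return FoldPlan(k=k, seed=seed, assignment=pd.Series(folds, index=list(animal_ids)))


def accuracy(gebv: np.ndarray, y_adj: np.ndarray, h2: float = 0.20) -> float:
    """Pearson correlation(GEBV, adjusted phenotype) / sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(y_adj, dtype=float)
    if g.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(g, y)[0, 1] / np.sqrt(h2))


def bias(gebv: np.ndarray, y_adj: np.ndarray, direction: str = "gebv_on_pheno") -> float:
    """OLS slope; default regresses GEBV on adjusted phenotype."""
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(y_adj, dtype=float)
    if direction == "gebv_on_pheno":
        x, t = y, g
    elif direction == "pheno_on_gebv":
        x, t = g, y
    else:
        raise ValueError(f"unknown direction {direction!r}")
    vx = np.var(x)
    if vx == 0:
        return np.nan
    return float(np.cov(x, t, bias=True)[0, 1] / vx)


@dataclass
class CvResult:
    """Per-fold accuracy/bias with their means and standard errors."""

    folds: pd.DataFrame  # fold, n_valid, accuracy, bias, bias_dispersion
    h2: float

    @property
    def accuracy_mean(self) -> float:
        return float(self.folds["accuracy"].mean())

    @property
    def accuracy_sem(self) -> float:
        return float(self.folds["accuracy"].std(ddof=1) / np.sqrt(len(self.folds)))

    @property
    def bias_mean(self) -> float:
        return float(self.folds["bias"].mean())

    @property
    def bias_sem(self) -> float:
        return float(self.folds["bias"].std(ddof=1) / np.sqrt(len(self.folds)))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "bias"],
                "mean": [self.accuracy_mean, self.bias_mean],
                "sem": [self.accuracy_sem, self.bias_sem],
            }
        )


def _build_matrix(
    g: PhasedGenotypes, calls: OriginCalls | None, ws: WindowSet | None, kind: str
):
    if kind == "control":
        m = build_control_xmatrix(g)
        return m.X, m.column_labels()
    if kind == "origin":
        if calls is None or ws is None:
            raise ValueError("origin matrix needs origin calls and a window set")
        m = build_origin_xmatrix(g, calls, ws)
        return m.X, m.column_labels()
    raise ValueError(f"unknown matrix kind {kind!r}")


def run_crossval(
    g: PhasedGenotypes,
    calls: OriginCalls | None,
    ph: PhenotypeTable,
    cfg: BayesRConfig,
    matrix_kind: str = "origin",
    ws: WindowSet | None = None,
    k: int = 5,
    h2: float = 0.20,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> CvResult:
    """k-fold cross-validated BayesR prediction on one design matrix.

    Origin assignment uses only the reference panel (no phenotypes), so the
    calls passed in are computed once outside the fold loop without
    leakage. Per fold, the sampler is trained on the remaining animals with
    cg + age fixed effects and the held-out animals are scored by
    GEBV = X ghat against their pre-adjusted phenotypes.
    """
    X, labels = _build_matrix(g, calls, ws, matrix_kind)
    pheno = ph.with_trait().set_index("animal_id", drop=False)
    ids = [a for a in g.animal_ids if a in pheno.index]
    if len(ids) < len(g.animal_ids):
        raise ValueError("phenotypes missing for some genotyped animals")
    y_adj = adjust_phenotypes(ph)
    if fold_plan is None:
        fold_plan = make_folds(ids, k=k, seed=seed)
    row_of = {a: i for i, a in enumerate(g.animal_ids)}
    rows = []
    for fold in range(fold_plan.k):
        train = fold_plan.training_ids(fold)
        valid = fold_plan.validation_ids(fold)
        tr = [row_of[a] for a in train]
        va = [row_of[a] for a in valid]
        Xtr = X[tr]
        model = BayesR(
            pheno.loc[train, "trait"].to_numpy(dtype=float),
            Xtr,
            fixed_data=pheno.loc[train],
            fixed=FixedEffectsSpec(factors=("cg",), covariates=("age",)),
            config=cfg,
            column_labels=labels,
        )
        res = model.fit(seed=seed * 1009 + fold)
        gebv = predict_gebv(X[va], res.effects_)
        ya = y_adj.loc[valid].to_numpy()
        rows.append(
            (
                fold,
                len(valid),
                accuracy(gebv, ya, h2),
                bias(gebv, ya, "gebv_on_pheno"),
                bias(gebv, ya, "pheno_on_gebv"),
            )
        )
    folds = pd.DataFrame(
        rows, columns=["fold", "n_valid", "accuracy", "bias", "bias_dispersion"]
    )
    return CvResult(folds=folds, h2=h2)


def qtl_report(
    res: BayesRResults,
    snp_map,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """SNP x origin-class rows with PIP_inclusion >= threshold, sorted by PIP.

    The returned frame is Manhattan-ready: chrom, pos, snp_id, class,
    effect, PIP. Column labels must have been attached to the fitted model.
    """
    if res.model.column_labels is None:
        raise ValueError("fitted model carries no column labels")
    eff = res.effects_frame()
    pos_of = dict(zip(snp_map.snp_id, snp_map.pos_bp))
    chrom_of = dict(zip(snp_map.snp_id, snp_map.chrom))
    out = eff.loc[eff["PIP_inclusion"] >= threshold].copy()
    out["chrom"] = out["snp_id"].map(chrom_of)
    out["pos"] = out["snp_id"].map(pos_of)
    out = out.sort_values("PIP_inclusion", ascending=False, kind="mergesort")
    return out[
        ["chrom", "pos", "snp_id", "class", "effect_mean", "PIP_inclusion"]
    ].reset_index(drop=True)


def plot_manhattan_panels(effects: pd.DataFrame, snp_map, path: str | None = None):
    """Minimal stacked Manhattan panels of PIP_inclusion, one per class.

    ``effects`` is an effects frame (snp_id, class, PIP_inclusion). Panels
    appear in Control/Bi/Bt/Bx order when present.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos_of = dict(zip(snp_map.snp_id, snp_map.pos_bp))
    chrom_of = dict(zip(snp_map.snp_id, snp_map.chrom))
    classes = [c for c in ("control", "Bi", "Bt", "Bx") if c in set(effects["class"])]
    fig, axes = plt.subplots(len(classes), 1, figsize=(8, 2 * len(classes)), sharex=True)
    if len(classes) == 1:
        axes = [axes]
    chroms = list(pd.unique(np.asarray(snp_map.chrom)))
    offset = {}
    acc = 0
    for c in chroms:
        offset[c] = acc
        acc += int(np.asarray(snp_map.pos_bp)[np.asarray(snp_map.chrom) == c].max())
    for ax, cls in zip(axes, classes):
        sub = effects.loc[effects["class"] == cls]
        x = [offset[chrom_of[s]] + pos_of[s] for s in sub["snp_id"]]
        ax.scatter(x, sub["PIP_inclusion"], s=4)
        ax.set_ylabel(cls)
        ax.set_ylim(0, 1.02)
    axes[-1].set_xlabel("genome position (bp, chromosomes concatenated)")
    fig.suptitle("Posterior inclusion probability by origin class")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
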