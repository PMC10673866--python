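"""Synthetic two-subspecies reference panels and hybrid target populations.

The generator emulates the study system end to end so every stage is
testable without real data:

* two ancestral pools diverged at a configurable Fst (Balding-Nichols
  frequency model) stand in for *Bos indicus* and *Bos taurus*;
* per subspecies, a small pool of founder haplotypes drawn from those
  frequencies is recombined by a copying process (exponential copy tracts),
  giving the haplotype sharing that makes window variants recur between
  reference and target animals;
* hybrid targets are ancestry mosaics: a Markov switch process along each
  chromosome (switch rate set by the generations-of-admixture parameter,
  1 cM/Mb) picks indicus/taurus tracts at the breed's expected indicus
  fraction, and alleles are copied from that subspecies' founders;
* origin-specific QTL effects (independent across subspecies by default)
  act through the TRUE origin design matrix; contemporary-group and age
  fixed effects plus a residual tuned to the target heritability complete
  the phenotype.

SNP-level truth is recorded per haplotype copy, so window-level truth can
be derived for any window grid (majority position within the window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PhasedGenotypes, PhenotypeTable, ReferenceLabels, SnpMap
from .windows import WindowSet

_MORGAN_BP = 1e8  # 1 cM/Mb


@dataclass(frozen=True)
class BreedProfile:
    name: str
    indicus_fraction: float
    generations: float  # generations of admixture, sets ancestry switch rate
    #: between-animal sd of the genome-wide indicus fraction. Stabilised
    #: composites and graded-up breeds are tight around their breed mean
    #: (a few points), far tighter than free segregation over a short
    #: simulated genome would give.
    fraction_sd: float = 0.03


@dataclass
class SimConfig:
    """Study conditions for the synthetic hybrid population.

    Defaults emulate the real system at desk scale: a dense uniform map,
    Fst 0.3 divergence, purebred reference panels, and three hybrid breed
    profiles at 90/50/37 % expected indicus content (a graded-up breed and
    two stabilised composites), with a lowly heritable 0-5 trait (h2 0.20).
    """

    n_snp: int = 2000
    n_chrom: int = 10
    snp_spacing_bp: int = 5000
    n_ref_bi: int = 100
    n_ref_bt: int = 100
    n_target_per_breed: int = 200
    breed_profiles: tuple[BreedProfile, ...] = (
        BreedProfile("graded_indicus", 0.90, 8.0),
        BreedProfile("composite_50", 0.50, 4.0),
        BreedProfile("composite_37", 0.37, 4.0),
    )
    divergence_fst: float = 0.3
    n_founders: int = 100  # founder haplotypes per subspecies (~cattle Ne)
    copy_tract_bp: float = 3e5  # expected founder-copying tract length
    n_qtl: int = 10
    qtl_variance_fraction: float = 1.0
    effect_correlation: float = 0.0  # Bi-vs-Bt allele effects
    qtl_effect_distribution: str = "normal"  # or "equal": unit magnitude, random sign
    qtl_min_maf: float = 0.10  # QTL must segregate within BOTH ancestral pools
    bx_effect_scale: float = 0.0  # heterosis-class effect sd, x the Bi/Bt sd
    h2: float = 0.20
    cg_levels: int = 5
    cg_sd: float = 0.5
    age_range: tuple[float, float] = (550.0, 650.0)
    age_effect: float = 0.002
    trait_mean: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.breed_profiles:
            if not 0.0 < p.indicus_fraction < 1.0:
                raise ValueError("indicus fractions must lie in (0, 1)")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")


#: named sub-streams, so each component is independently reproducible
_STREAMS = ("pools", "panel", "hybrids", "effects", "phenotypes")


def _rng(cfg: SimConfig, name: str) -> np.random.Generator:
    key = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(key,)))


def _uniform_map(cfg: SimConfig) -> SnpMap:
    per_chrom = cfg.n_snp // cfg.n_chrom
    counts = [per_chrom] * cfg.n_chrom
    counts[-1] += cfg.n_snp - per_chrom * cfg.n_chrom
    chrom, pos, sid = [], [], []
    for c, m in enumerate(counts, start=1):
        for j in range(m):
            chrom.append(str(c))
            pos.append((j + 1) * cfg.snp_spacing_bp)
            sid.append(f"snp{c}_{j + 1}")
    n = len(sid)
    return SnpMap(
        snp_id=np.array(sid, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ref_allele=np.array(["A"] * n, dtype=object),
        alt_allele=np.array(["B"] * n, dtype=object),
    )


@dataclass
class AncestralPools:
    """Diverged subspecies allele frequencies plus founder haplotype pools."""

    map: SnpMap
    p_ancestral: np.ndarray
    p_bi: np.ndarray
    p_bt: np.ndarray
    founders_bi: np.ndarray  # (n_founders, n_snp) uint8
    founders_bt: np.ndarray


def simulate_ancestral_pools(cfg: SimConfig) -> AncestralPools:
    """Balding-Nichols divergence of two subspecies from a common ancestor.

    Each subspecies' allele frequency at a SNP is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, giving
    expected Fst F between the pools. Founder haplotypes for the copying
    model are drawn SNP-wise from each subspecies' frequencies.
    """
    rng = _rng(cfg, "pools")
    smap = _uniform_map(cfg)
    n = smap.n_snp
    p_anc = rng.uniform(0.1, 0.9, size=n)
    fst = cfg.divergence_fst
    if fst <= 0:
        p_bi = p_anc.copy()
        p_bt = p_anc.copy()
    else:
        c = (1.0 - fst) / fst
        p_bi = rng.beta(p_anc * c, (1.0 - p_anc) * c)
        p_bt = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    founders_bi = (rng.random((cfg.n_founders, n)) < p_bi).astype(np.uint8)
    founders_bt = (rng.random((cfg.n_founders, n)) < p_bt).astype(np.uint8)
    return AncestralPools(smap, p_anc, p_bi, p_bt, founders_bi, founders_bt)


def _switch_segments(
    rng: np.random.Generator, n_hap: int, smap: SnpMap, rate_per_bp: float
) -> np.ndarray:
    """Boolean (n_hap, n_snp) marking positions where a new tract starts.

    The first SNP of each chromosome always starts a tract; between
    consecutive SNPs at distance d the switch probability is 1-exp(-rate*d).
    """
    chrom = np.asarray(smap.chrom)
    pos = np.asarray(smap.pos_bp).astype(float)
    d = np.diff(pos)
    new_chrom = chrom[1:] != chrom[:-1]
    p_switch = 1.0 - np.exp(-rate_per_bp * d)
    p_switch[new_chrom] = 1.0
    ev = np.empty((n_hap, smap.n_snp), dtype=bool)
    ev[:, 0] = True
    ev[:, 1:] = rng.random((n_hap, smap.n_snp - 1)) < p_switch
    return ev


def _forward_fill_index(event: np.ndarray) -> np.ndarray:
    """Per row, the column index of the most recent True at or before j."""
    cols = np.arange(event.shape[1])
    idx = np.where(event, cols, 0)
    return np.maximum.accumulate(idx, axis=1)


def _copy_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    n_hap: int,
    smap: SnpMap,
    copy_tract_bp: float,
    extra_event: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mosaic haplotypes copied from a founder pool.

    Returns (alleles, founder_index) arrays of shape (n_hap, n_snp).
    ``extra_event`` forces additional re-draws of the copied founder (used
    at ancestry switch points in hybrids).
    """
    event = _switch_segments(rng, n_hap, smap, 1.0 / copy_tract_bp)
    if extra_event is not None:
        event |= extra_event
    draws = rng.integers(0, founders.shape[0], size=event.shape)
    src = _forward_fill_index(event)
    rows = np.arange(n_hap)[:, None]
    founder_idx = draws[rows, src]
    alleles = founders[founder_idx, np.arange(event.shape[1])[None, :]]
    return alleles, founder_idx


def simulate_reference_panel(
    cfg: SimConfig, pools: AncestralPools
) -> tuple[PhasedGenotypes, ReferenceLabels]:
    """Purebred reference animals copied from their subspecies' founders."""
    rng = _rng(cfg, "panel")
    smap = pools.map
    out = []
    for founders, n_animals in ((pools.founders_bi, cfg.n_ref_bi), (pools.founders_bt, cfg.n_ref_bt)):
        alleles, _ = _copy_haplotypes(rng, founders, 2 * n_animals, smap, cfg.copy_tract_bp)
        out.append(alleles.reshape(n_animals, 2, smap.n_snp).transpose(0, 2, 1))
    alleles = np.concatenate(out, axis=0).astype(np.uint8)
    ids = [f"bi{i:04d}" for i in range(cfg.n_ref_bi)] + [
        f"bt{i:04d}" for i in range(cfg.n_ref_bt)
    ]
    labels = ReferenceLabels(
        pd.DataFrame(
            {
                "animal_id": ids,
                "subspecies": ["indicus"] * cfg.n_ref_bi + ["taurus"] * cfg.n_ref_bt,
                "breed": ["sim_indicus"] * cfg.n_ref_bi + ["sim_taurus"] * cfg.n_ref_bt,
            }
        )
    )
    return PhasedGenotypes(ids, smap, alleles), labels


@dataclass
class TruthTracks:
    """Ground truth for the simulated targets.

    ``snp_ancestry[a, j, c]`` is 1 when copy c of animal a is indicus at
    SNP j, so window truth follows for any grid. QTL indices/effects and
    true breeding values are filled once phenotypes are simulated.
    """

    animal_ids: list[str]
    breed_of: dict[str, str]
    snp_ancestry: np.ndarray  # (n, n_snp, 2) uint8
    qtl_indices: np.ndarray | None = None
    qtl_effects: dict[str, np.ndarray] | None = None  # class -> per-QTL effect
    tbv: np.ndarray | None = None
    map: SnpMap | None = None

    def window_ancestry(self, ws: WindowSet) -> np.ndarray:
        """(n, n_windows, 2) true per-copy window ancestry by majority SNP.

        With a uniform map this equals majority bp of the tract ancestry
        within the window; ties go to indicus, mirroring the caller's
        b >= 0.5 convention.
        """
        n = self.snp_ancestry.shape[0]
        out = np.empty((n, ws.n_windows, 2), dtype=np.uint8)
        for k, w in enumerate(ws.windows):
            block = self.snp_ancestry[:, w.snp_slice, :]
            out[:, k, :] = (block.mean(axis=1) >= 0.5).astype(np.uint8)
        return out

    def indicus_fraction(self) -> np.ndarray:
        return self.snp_ancestry.mean(axis=(1, 2))

    def true_diplotype_class(self) -> np.ndarray:
        """(n, n_snp) SNP-level class index: 0=Bi, 1=Bt, 2=Bx."""
        s = self.snp_ancestry.sum(axis=2)
        return np.where(s == 2, 0, np.where(s == 0, 1, 2))


def _quota_ancestry(
    rng: np.random.Generator,
    anc_event: np.ndarray,
    n_animals: int,
    target_fraction: np.ndarray,
) -> np.ndarray:
    """Assign tract ancestries per animal to hit a genome-wide quota.

    ``anc_event`` marks tract starts for the 2*n_animals haplotype rows
    (animal a owns rows 2a and 2a+1). Tracts are visited in random order
    and flagged indicus until the animal's indicus SNP count reaches
    ``target_fraction[a]`` of its genome, reproducing the tight
    within-breed ancestry spread of stabilised composites while keeping
    ancestry locally contiguous.
    """
    n_hap, n_snp = anc_event.shape
    ancestry = np.zeros((n_hap, n_snp), dtype=bool)
    for a in range(n_animals):
        tracts = []  # (row, start, stop)
        for row in (2 * a, 2 * a + 1):
            starts = np.flatnonzero(anc_event[row])
            stops = np.append(starts[1:], n_snp)
            tracts += [(row, s, e) for s, e in zip(starts, stops)]
        order = rng.permutation(len(tracts))
        quota = target_fraction[a] * 2 * n_snp
        filled = 0
        for t in order:
            row, s, e = tracts[t]
            length = e - s
            # take the crossing tract only if that lands closer to quota
            if filled + length - quota > quota - filled:
                continue
            ancestry[row, s:e] = True
            filled += length
            if filled >= quota:
                break
    return ancestry


def simulate_hybrids(
    cfg: SimConfig, pools: AncestralPools
) -> tuple[PhasedGenotypes, TruthTracks]:
    """Hybrid targets as ancestry mosaics over the two founder pools."""
    rng = _rng(cfg, "hybrids")
    smap = pools.map
    all_alleles, all_anc, ids, breed_of = [], [], [], {}
    for prof in cfg.breed_profiles:
        n_hap = 2 * cfg.n_target_per_breed
        rate = prof.generations / _MORGAN_BP
        anc_event = _switch_segments(rng, n_hap, smap, rate)
        target = np.clip(
            rng.normal(prof.indicus_fraction, prof.fraction_sd, cfg.n_target_per_breed),
            0.02,
            0.98,
        )
        ancestry = _quota_ancestry(rng, anc_event, cfg.n_target_per_breed, target)
        alleles_bi, _ = _copy_haplotypes(
            rng, pools.founders_bi, n_hap, smap, cfg.copy_tract_bp, extra_event=anc_event
        )
        alleles_bt, _ = _copy_haplotypes(
            rng, pools.founders_bt, n_hap, smap, cfg.copy_tract_bp, extra_event=anc_event
        )
        alleles = np.where(ancestry, alleles_bi, alleles_bt)
        n = cfg.n_target_per_breed
        all_alleles.append(alleles.reshape(n, 2, smap.n_snp).transpose(0, 2, 1))
        all_anc.append(ancestry.reshape(n, 2, smap.n_snp).transpose(0, 2, 1))
        bids = [f"{prof.name}_{i:04d}" for i in range(n)]
        ids += bids
        breed_of.update({a: prof.name for a in bids})
    g = PhasedGenotypes(ids, smap, np.concatenate(all_alleles).astype(np.uint8))
    truth = TruthTracks(
        animal_ids=ids,
        breed_of=breed_of,
        snp_ancestry=np.concatenate(all_anc).astype(np.uint8),
        map=smap,
    )
    return g, truth


def assign_qtl_effects(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    n_snp: int | None = None,
    candidates: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pick QTL SNPs and draw per-origin allele effects.

    Bi and Bt effects are bivariate normal with the configured correlation
    (0 by default: effects arose independently after divergence); the Bx
    (heterosis) effect is an independent draw scaled by ``bx_effect_scale``.
    With ``qtl_effect_distribution="equal"`` every QTL gets a unit-magnitude
    effect of random sign per origin instead, so each contributes a
    comparable variance share (a Gaussian draw plants "QTL" of negligible
    effect that no method could detect). ``"ghost"`` draws the classic
    ghost-QTL architecture: each QTL has a unit-magnitude effect in exactly
    one subspecies of origin and none in the other — the scenario
    origin-partitioned models exist for.
    """
    rng = rng or _rng(cfg, "effects")
    n_snp = n_snp if n_snp is not None else cfg.n_snp
    if cfg.n_qtl == 0:
        return np.empty(0, dtype=np.int64), {
            "Bi": np.empty(0),
            "Bt": np.empty(0),
            "Bx": np.empty(0),
        }
    pool = candidates if candidates is not None else np.arange(n_snp)
    if len(pool) < cfg.n_qtl:
        raise ValueError("fewer candidate SNPs than requested QTL")
    idx = np.sort(rng.choice(pool, size=cfg.n_qtl, replace=False))
    rho = cfg.effect_correlation
    if cfg.qtl_effect_distribution == "equal":
        bi = rng.choice([-1.0, 1.0], size=cfg.n_qtl)
        bt = bi if rho == 1.0 else rng.choice([-1.0, 1.0], size=cfg.n_qtl)
        bi_bt = np.column_stack([bi, bt])
    elif cfg.qtl_effect_distribution == "ghost":
        sign = rng.choice([-1.0, 1.0], size=cfg.n_qtl)
        in_bi = rng.random(cfg.n_qtl) < 0.5
        bi_bt = np.column_stack([np.where(in_bi, sign, 0.0), np.where(in_bi, 0.0, sign)])
    elif cfg.qtl_effect_distribution == "normal":
        cov = np.array([[1.0, rho], [rho, 1.0]])
        bi_bt = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_qtl)
        if rho == 1.0:
            bi_bt[:, 1] = bi_bt[:, 0]
    else:
        raise ValueError(f"unknown effect distribution {cfg.qtl_effect_distribution!r}")
    bx = cfg.bx_effect_scale * rng.standard_normal(cfg.n_qtl)
    if rho == 1.0 and cfg.qtl_effect_distribution != "ghost":
        # fully origin-independent loci: the heterozygous-origin class
        # carries the same per-allele effect as the two homozygous classes
        bx = bx + bi_bt[:, 0]
    return idx, {"Bi": bi_bt[:, 0], "Bt": bi_bt[:, 1], "Bx": bx}


def _true_breeding_values(
    g: PhasedGenotypes,
    truth: TruthTracks,
    qtl_idx: np.ndarray,
    effects: dict[str, np.ndarray],
) -> np.ndarray:
    """TBV through the TRUE origin design: dosage x the class's effect."""
    if len(qtl_idx) == 0:
        return np.zeros(g.n_animals)
    dos = g.dosages()[:, qtl_idx].astype(float)
    cls = truth.true_diplotype_class()[:, qtl_idx]
    eff = np.stack([effects["Bi"], effects["Bt"], effects["Bx"]])  # (3, nqtl)
    per_qtl = eff[cls, np.arange(len(qtl_idx))[None, :]]
    return (dos * per_qtl).sum(axis=1)


def simulate_phenotypes(
    g: PhasedGenotypes,
    truth: TruthTracks,
    cfg: SimConfig,
    pools: AncestralPools | None = None,
) -> PhenotypeTable:
    """Phenotypes = mean + cg + age + TBV + e at the configured heritability.

    Contemporary groups are nested within breed (the real design has no
    mixed-breed groups). The residual variance is set from the realised
    TBV variance so that var(TBV)/var(TBV + e) = h2 up to sampling error.
    QTL positions/effects are drawn here (stream "effects") and recorded on
    ``truth``; with ``qtl_variance_fraction < 1`` the remaining genetic
    variance is spread over a small-effect polygenic background.
    """
    eff_rng = _rng(cfg, "effects")
    rng = _rng(cfg, "phenotypes")
    lo, hi = cfg.qtl_min_maf, 1.0 - cfg.qtl_min_maf
    if pools is not None:
        # a subspecies-specific effect is only visible if the SNP
        # segregates within that subspecies, so require both pools
        seg = (pools.p_bi >= lo) & (pools.p_bi <= hi) & (pools.p_bt >= lo) & (
            pools.p_bt <= hi
        )
        candidates = np.flatnonzero(seg)
    else:
        freq = g.dosages().mean(axis=0) / 2.0
        candidates = np.flatnonzero((freq >= lo) & (freq <= hi))
    if len(candidates) < cfg.n_qtl:
        candidates = None  # fall back to the full map on tiny fixtures
    qtl_idx, effects = assign_qtl_effects(cfg, eff_rng, g.n_snp, candidates)
    tbv = _true_breeding_values(g, truth, qtl_idx, effects)
    if cfg.qtl_variance_fraction < 1.0 and g.n_snp > cfg.n_qtl:
        n_poly = min(500, g.n_snp - cfg.n_qtl)
        pool = np.setdiff1d(np.arange(g.n_snp), qtl_idx)
        poly_idx = np.sort(eff_rng.choice(pool, size=n_poly, replace=False))
        poly_eff = {
            c: eff_rng.standard_normal(n_poly) / np.sqrt(n_poly) for c in ("Bi", "Bt")
        }
        poly_eff["Bx"] = np.zeros(n_poly)
        poly = _true_breeding_values(g, truth, poly_idx, poly_eff)
        vq, vp = np.var(tbv), np.var(poly)
        f = cfg.qtl_variance_fraction
        if vq > 0 and vp > 0:
            tbv = tbv + poly * np.sqrt((1 - f) / f * vq / vp)
    # rescale to unit genic variance: var(TBV) = h2, sigma_e^2 = 1 - h2,
    # keeping the trait near its 0-5 scale
    var_g = float(np.var(tbv))
    if var_g > 0:
        s = np.sqrt(cfg.h2 / var_g)
        tbv = tbv * s
        effects = {c: v * s for c, v in effects.items()}
        sigma_e = np.sqrt(1.0 - cfg.h2)
    else:
        sigma_e = 1.0
    truth.qtl_indices = qtl_idx
    truth.qtl_effects = effects
    truth.tbv = tbv

    n = g.n_animals
    breeds = [truth.breed_of[a] for a in g.animal_ids]
    cg = []
    per_breed_counter: dict[str, int] = {}
    for b in breeds:
        i = per_breed_counter.get(b, 0)
        per_breed_counter[b] = i + 1
        cg.append(f"{b}_cg{i % cfg.cg_levels}")
    cg = pd.Series(cg)
    cg_eff = {lev: rng.normal(0.0, cfg.cg_sd) for lev in cg.unique()}
    age = rng.uniform(*cfg.age_range, size=n)
    e = rng.normal(0.0, sigma_e, size=n)
    trait = (
        cfg.trait_mean
        + cg.map(cg_eff).to_numpy()
        + cfg.age_effect * (age - np.mean(cfg.age_range))
        + tbv
        + e
    )
    return PhenotypeTable(
        pd.DataFrame(
            {
                "animal_id": g.animal_ids,
                "trait": trait,
                "cg": pd.Categorical(cg),
                "age": age,
                "breed": pd.Categorical(breeds),
            }
        )
    )


@dataclass
class SimStudy:
    """One fully simulated study: panel, targets, truth and phenotypes."""

    config: SimConfig
    pools: AncestralPools
    reference: PhasedGenotypes
    labels: ReferenceLabels
    targets: PhasedGenotypes
    truth: TruthTracks
    phenotypes: PhenotypeTable = field(repr=False)


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Run the whole generator under one seed (named sub-streams inside)."""
    pools = simulate_ancestral_pools(cfg)
    ref, labels = simulate_reference_panel(cfg, pools)
    targets, truth = simulate_hybrids(cfg, pools)
    pheno = simulate_phenotypes(targets, truth, cfg, pools)
    return SimStudy(cfg, pools, ref, labels, targets, truth, pheno)
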