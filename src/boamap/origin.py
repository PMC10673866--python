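"""Subspecies-of-origin assignment of haplotypes from reference frequencies.

Each target haplotype variant gets a b-value, the probability it is
*Bos indicus* in origin:

    b = pBi / (pBi + pBt)

where pBi/pBt are the variant's frequencies among the indicus/taurus
reference haplotypes in that window. A haplotype is called Bi when
b >= 0.5, Bt otherwise. Variants absent from both reference subspecies are
resolved by Hamming distances to the reference haplotype copies; the two
haplotype calls combine into a window diplotype class Bi / Bt / Bx
(homozygous indicus, homozygous taurus, heterozygous indicus x taurus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import HaplotypeFrequencyTable, WindowSet

BI, BT, BX = "Bi", "Bt", "Bx"

#: haplotype-call codes used in array storage
_HAP_BI, _HAP_BT = 1, 0
_DIP = {(1, 1): BI, (0, 0): BT, (0, 1): BX, (1, 0): BX}


def b_value(p_bi: float, p_bt: float) -> float:
    """Probability a haplotype variant is B. indicus in origin.

    Raises if both frequencies are zero: an unseen variant must be routed
    through :func:`hamming_fallback`.
    """
    if p_bi < 0 or p_bt < 0:
        raise ValueError("frequencies must be non-negative")
    tot = p_bi + p_bt
    if tot == 0:
        raise ZeroDivisionError("unseen haplotype, use fallback")
    return p_bi / tot


def classify_haplotype(b: float) -> str:
    """Bi iff b >= 0.5 (ties to indicus, as the inequality directs)."""
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    return BI if b >= 0.5 else BT


def classify_diplotype(o0: str, o1: str) -> str:
    """Combine two haplotype origins into the window diplotype class."""
    key = (1 if o0 == BI else 0, 1 if o1 == BI else 0)
    for o in (o0, o1):
        if o not in (BI, BT):
            raise ValueError(f"haplotype origin must be Bi or Bt, got {o!r}")
    return _DIP[key]


def _popcount(x: int) -> int:
    return int(x).bit_count()


def hamming_fallback(
    query: int,
    refs_bi: dict[int, int],
    refs_bt: dict[int, int],
    mode: str = "as_printed",
    normalise: bool = False,
) -> tuple[float, float, str]:
    """Resolve a variant unseen in both subspecies by Hamming distances.

    Distances from the query code to every reference haplotype copy are
    summed per subspecies (``refs_*`` map code -> copy multiplicity).

    mode="as_printed"
        Prob(Bi) = sum(Bi) / (sum(Bi) + sum(Bt)) and the haplotype is
        allocated to the larger probability — i.e. to the subspecies whose
        copies are on average *farther* from the query.
    mode="similarity"
        Distances are first averaged per reference copy and the haplotype
        goes to the *smaller* mean distance; the reported probabilities are
        the complementary normalised similarities.

    With ``normalise`` the per-subspecies sums are divided by the number of
    reference copies before the as_printed ratio, removing the panel-size
    imbalance. Ties assign Bi, mirroring the b >= 0.5 convention.
    """
    if not refs_bi or not refs_bt:
        raise ValueError("both reference lists must be non-empty")
    if mode not in ("as_printed", "similarity"):
        raise ValueError(f"unknown fallback mode {mode!r}")

    def total(refs: dict[int, int]) -> tuple[float, int]:
        s = 0
        n = 0
        for code, mult in refs.items():
            s += _popcount(query ^ code) * mult
            n += mult
        return float(s), n

    sum_bi, n_bi = total(refs_bi)
    sum_bt, n_bt = total(refs_bt)
    if mode == "as_printed":
        a, b = (sum_bi / n_bi, sum_bt / n_bt) if normalise else (sum_bi, sum_bt)
        if a + b == 0:  # query identical to every reference copy
            prob_bi = prob_bt = 0.5
        else:
            prob_bi, prob_bt = a / (a + b), b / (a + b)
        assigned = BI if prob_bi >= prob_bt else BT
    else:
        mean_bi, mean_bt = sum_bi / n_bi, sum_bt / n_bt
        tot = mean_bi + mean_bt
        if tot == 0:
            prob_bi = prob_bt = 0.5
        else:
            # complementary normalised similarity: small distance, large prob
            prob_bi, prob_bt = mean_bt / tot, mean_bi / tot
        assigned = BI if mean_bi <= mean_bt else BT
    return prob_bi, prob_bt, assigned


@dataclass
class OriginCalls:
    """Per animal x window origin calls with b-value provenance.

    ``hap_origin[a, k, c]`` is 1 for Bi, 0 for Bt; ``diplotype[a, k]`` is
    one of "Bi"/"Bt"/"Bx"; ``b_values`` stores the per-haplotype assignment
    probability and ``source`` whether it came from reference frequencies
    or the Hamming fallback.
    """

    animal_ids: list[str]
    window_set: WindowSet
    hap_origin: np.ndarray  # (nanim, nwin, 2) uint8
    b_values: np.ndarray  # (nanim, nwin, 2) float
    source: np.ndarray  # (nanim, nwin, 2) of {"frequency","hamming"}

    @property
    def n_animals(self) -> int:
        return self.hap_origin.shape[0]

    def diplotype(self, a: int, k: int) -> str:
        return _DIP[(int(self.hap_origin[a, k, 0]), int(self.hap_origin[a, k, 1]))]

    def diplotypes(self) -> np.ndarray:
        """(nanim, nwin) array of "Bi"/"Bt"/"Bx" strings."""
        s = self.hap_origin.sum(axis=2)
        out = np.where(s == 2, BI, np.where(s == 0, BT, BX))
        return out.astype(object)

    def fallback_fraction(self) -> float:
        return float(np.mean(self.source == "hamming"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        lab = {1: BI, 0: BT}
        for a, aid in enumerate(self.animal_ids):
            for k, w in enumerate(self.window_set.windows):
                rows.append(
                    (
                        aid,
                        w.chrom,
                        w.start_bp,
                        w.end_bp,
                        lab[int(self.hap_origin[a, k, 0])],
                        lab[int(self.hap_origin[a, k, 1])],
                        self.diplotype(a, k),
                        self.b_values[a, k, 0],
                        self.b_values[a, k, 1],
                        self.source[a, k, 0],
                        self.source[a, k, 1],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "animal_id",
                "chrom",
                "window_start",
                "window_end",
                "hap0",
                "hap1",
                "diplotype",
                "b0",
                "b1",
                "source0",
                "source1",
            ],
        )


def assign_origins(
    target_codes: np.ndarray,
    animal_ids: list[str],
    freq_table: HaplotypeFrequencyTable,
    mode: str = "as_printed",
    normalise_fallback: bool = False,
) -> OriginCalls:
    """Assign subspecies of origin to every target haplotype.

    Seen variants (nonzero frequency in at least one reference subspecies)
    are called through the b-value; variants absent from both panels go
    through :func:`hamming_fallback` in the requested mode.
    """
    ws = freq_table.window_set
    n_anim, n_win, _ = target_codes.shape
    if n_win != ws.n_windows:
        raise ValueError("target codes cover windows absent from the frequency table")
    hap = np.zeros((n_anim, n_win, 2), dtype=np.uint8)
    bvals = np.zeros((n_anim, n_win, 2), dtype=float)
    src = np.empty((n_anim, n_win, 2), dtype=object)
    for k in range(n_win):
        table = freq_table.tables[k]
        refs_bi = {c: n[0] for c, n in table.items() if n[0] > 0}
        refs_bt = {c: n[1] for c, n in table.items() if n[1] > 0}
        cache: dict[int, tuple[int, float, str]] = {}
        for a in range(n_anim):
            for c in (0, 1):
                code = int(target_codes[a, k, c])
                hit = cache.get(code)
                if hit is None:
                    p_bi, p_bt = freq_table.freqs(k, code)
                    if p_bi + p_bt > 0:
                        b = b_value(p_bi, p_bt)
                        call = classify_haplotype(b)
                        hit = (_HAP_BI if call == BI else _HAP_BT, b, "frequency")
                    else:
                        prob_bi, _, assigned = hamming_fallback(
                            code, refs_bi, refs_bt, mode, normalise_fallback
                        )
                        hit = (
                            _HAP_BI if assigned == BI else _HAP_BT,
                            prob_bi,
                            "hamming",
                        )
                    cache[code] = hit
                hap[a, k, c], bvals[a, k, c], src[a, k, c] = hit
    return OriginCalls(
        animal_ids=list(animal_ids),
        window_set=ws,
        hap_origin=hap,
        b_values=bvals,
        source=src,
    )


def indicus_percentage(
    calls: OriginCalls,
    weighting: str = "per_haplotype",
    breeds: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-animal B. indicus percentage, optionally summarised per breed.

    per_haplotype (default): % = 100 x (Bi copies) / (2 x windows);
    per_snp weights each window by its SNP count m.
    """
    if weighting not in ("per_haplotype", "per_snp"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "per_haplotype":
        w = np.ones(calls.window_set.n_windows)
    else:
        w = calls.window_set.m_per_window().astype(float)
    bi_copies = calls.hap_origin.sum(axis=2)  # (nanim, nwin) in {0,1,2}
    pct = 100.0 * (bi_copies * w).sum(axis=1) / (2.0 * w.sum())
    per_animal = pd.Series(pct, index=calls.animal_ids, name="indicus_pct")
    per_breed = None
    if breeds is not None:
        df = per_animal.to_frame()
        df["breed"] = [breeds[a] for a in calls.animal_ids]
        per_breed = (
            df.groupby("breed", sort=True)["indicus_pct"]
            .agg(["mean", "std", "min", "max"])
            .rename(columns={"std": "sd"})
        )
    return per_animal, per_breed
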