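"""Fixed non-overlapping haplotype windows and reference variant frequencies.

The genome is cut into fixed bp windows (50/100/250 kb are the standard
sizes) anchored at bp 1 of each chromosome: a SNP at 1-based position p
falls in within-chromosome window ``floor((p-1)/W)``. Each chromosome copy
of each animal then carries one haplotype variant per window — the ordered
alleles over the window's SNP, bit-packed into an integer code (up to 2^m
variants for m SNP). Variant frequencies tallied per subspecies in a
purebred reference panel are the basis for subspecies-of-origin assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhasedGenotypes, ReferenceLabels, SnpMap

#: windows with more SNP than this cannot be packed into a uint64 code and
#: fall back to byte-string codes
_PACK_LIMIT = 63


@dataclass(frozen=True)
class Window:
    chrom: str
    start_bp: int  # 0-based inclusive
    end_bp: int  # 0-based exclusive
    snp_slice: slice  # contiguous range into the map

    @property
    def m(self) -> int:
        return self.snp_slice.stop - self.snp_slice.start


@dataclass
class WindowSet:
    """Non-overlapping windows covering every mapped SNP exactly once."""

    window_kb: int
    windows: list[Window]
    map: SnpMap

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def m_per_window(self) -> np.ndarray:
        return np.array([w.m for w in self.windows], dtype=np.int64)

    def snp_window_index(self) -> np.ndarray:
        """For each SNP (map order), the index of its window."""
        out = np.empty(self.map.n_snp, dtype=np.int64)
        for k, w in enumerate(self.windows):
            out[w.snp_slice] = k
        return out


def build_windows(snp_map: SnpMap, window_kb: int) -> WindowSet:
    """Partition the map into fixed ``window_kb`` windows per chromosome.

    Zero-SNP windows are dropped; trailing partial windows are kept. The
    grid is anchored at bp 1 so the SNP at 1-based position p belongs to
    within-chromosome window ``floor((p-1)/(window_kb*1000))``; window
    bounds are reported 0-based half-open.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if snp_map.n_snp == 0:
        raise ValueError("empty SNP map")
    wbp = window_kb * 1000
    chrom = np.asarray(snp_map.chrom)
    pos = np.asarray(snp_map.pos_bp)
    windows: list[Window] = []
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        widx = (pos[idx] - 1) // wbp
        # SNPs are position-sorted per chromosome, so equal window indices
        # are contiguous runs
        for k in pd.unique(widx):
            sel = idx[widx == k]
            windows.append(
                Window(
                    chrom=str(c),
                    start_bp=int(k) * wbp,
                    end_bp=(int(k) + 1) * wbp,
                    snp_slice=slice(int(sel[0]), int(sel[-1]) + 1),
                )
            )
        start += len(idx)
    return WindowSet(window_kb=window_kb, windows=windows, map=snp_map)


def mean_snps_per_window(ws: WindowSet) -> float:
    """Arithmetic mean SNP count over retained windows."""
    return float(ws.m_per_window().mean())


def encode_haplotypes(g: PhasedGenotypes, ws: WindowSet) -> np.ndarray:
    """Bit-pack each animal's two haplotypes per window.

    Returns an object array of shape (n_animals, n_windows, 2); entries are
    Python ints (map-order big-endian packing: the window's first SNP is the
    most significant bit), so windows of any m are handled exactly.
    """
    if g.map is not ws.map and not (
        np.array_equal(g.map.snp_id, ws.map.snp_id)
        and np.array_equal(g.map.pos_bp, ws.map.pos_bp)
    ):
        raise ValueError("genotype map does not match the map used to build windows")
    codes = np.empty((g.n_animals, ws.n_windows, 2), dtype=object)
    for k, w in enumerate(ws.windows):
        block = g.alleles[:, w.snp_slice, :]  # (nanim, m, 2)
        weights = 1 << np.arange(w.m - 1, -1, -1, dtype=object)
        for c in (0, 1):
            codes[:, k, c] = block[:, :, c].astype(object) @ weights
    return codes


def decode_haplotype(code: int, m: int) -> np.ndarray:
    """Unpack a variant code back to its m-allele 0/1 vector (map order)."""
    if code < 0 or code >= (1 << m):
        raise ValueError("code out of range for window size")
    return np.array([(code >> (m - 1 - j)) & 1 for j in range(m)], dtype=np.uint8)


@dataclass
class HaplotypeFrequencyTable:
    """Per-window variant counts and frequencies in each reference subspecies.

    ``tables[k]`` maps variant code -> (count_Bi, count_Bt) for window k;
    counts are over haplotype copies (two per reference animal).
    """

    window_set: WindowSet
    tables: list[dict[int, tuple[int, int]]]
    n_hap_bi: int
    n_hap_bt: int

    def freqs(self, window: int, code: int) -> tuple[float, float]:
        cBi, cBt = self.tables[window].get(code, (0, 0))
        return cBi / self.n_hap_bi, cBt / self.n_hap_bt

    def counts(self, window: int, code: int) -> tuple[int, int]:
        return self.tables[window].get(code, (0, 0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, w in enumerate(self.window_set.windows):
            for code, (cBi, cBt) in sorted(self.tables[k].items()):
                rows.append(
                    (
                        w.chrom,
                        w.start_bp,
                        w.end_bp,
                        format(code, "x"),
                        cBi,
                        cBt,
                        cBi / self.n_hap_bi,
                        cBt / self.n_hap_bt,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "window_start",
                "window_end",
                "code_hex",
                "count_Bi",
                "count_Bt",
                "freq_Bi",
                "freq_Bt",
            ],
        )


def reference_frequencies(
    codes: np.ndarray, animal_ids: list[str], labels: ReferenceLabels, ws: WindowSet
) -> HaplotypeFrequencyTable:
    """Tally variant counts per window and subspecies over reference copies.

    ``codes`` is the (n_animals, n_windows, 2) array from
    :func:`encode_haplotypes` for the reference panel; every coded animal
    must carry a subspecies label.
    """
    lab = dict(zip(labels.frame["animal_id"], labels.frame["subspecies"]))
    missing = [a for a in animal_ids if a not in lab]
    if missing:
        raise ValueError(f"unlabelled reference animals: {missing[:5]}")
    bi_rows = [i for i, a in enumerate(animal_ids) if lab[a] == "indicus"]
    bt_rows = [i for i, a in enumerate(animal_ids) if lab[a] == "taurus"]
    if not bi_rows or not bt_rows:
        raise ValueError("a subspecies has zero reference animals")
    tables: list[dict[int, tuple[int, int]]] = []
    for k in range(ws.n_windows):
        table: dict[int, tuple[int, int]] = {}
        for rows, which in ((bi_rows, 0), (bt_rows, 1)):
            for i in rows:
                for c in (0, 1):
                    code = int(codes[i, k, c])
                    cur = table.get(code, (0, 0))
                    table[code] = (
                        (cur[0] + 1, cur[1]) if which == 0 else (cur[0], cur[1] + 1)
                    )
        tables.append(table)
    return HaplotypeFrequencyTable(
        window_set=ws,
        tables=tables,
        n_hap_bi=2 * len(bi_rows),
        n_hap_bt=2 * len(bt_rows),
    )
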