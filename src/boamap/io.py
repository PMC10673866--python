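"""Readers and writers for phased genotypes, SNP maps, phenotypes and labels.

The package works from phased, bi-allelic, complete genotypes: phasing and
imputation happen upstream. Two genotype sources are supported, a phased VCF
(parsed with cyvcf2) and a plain haplotype TSV dialect documented in
:func:`write_haplotype_tsv`. All tabular outputs are TSV with ``#``-prefixed
header lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GenotypeFormatError(ValueError):
    """Malformed or unsupported genotype input."""


@dataclass(frozen=True)
class SnpMap:
    """Physical SNP map: id, chromosome and 1-based bp position per SNP.

    Positions must be strictly increasing within each chromosome; ids unique.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chrom", "pos_bp", "ref_allele", "alt_allele"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name!r} length mismatch")
        if len(set(self.snp_id)) != n:
            raise ValueError("duplicate snp_id in map")
        pos = np.asarray(self.pos_bp)
        if n and pos.min() < 1:
            raise ValueError("pos_bp must be >= 1 (1-based)")
        for c in pd.unique(np.asarray(self.chrom)):
            p = pos[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snp(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "ref": self.ref_allele,
                "alt": self.alt_allele,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMap":
        return cls(
            snp_id=df["snp_id"].to_numpy(dtype=object),
            chrom=df["chrom"].astype(str).to_numpy(dtype=object),
            pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
            ref_allele=df["ref"].astype(str).to_numpy(dtype=object),
            alt_allele=df["alt"].astype(str).to_numpy(dtype=object),
        )


@dataclass
class PhasedGenotypes:
    """Phased genotypes: ``alleles[animal, snp, copy] in {0, 1}``.

    Copy 0 is the first (paternal) haplotype, copy 1 the second (maternal).
    Dosage is the per-SNP allele sum, the 0/1/2 coding of the alternative
    allele count.
    """

    animal_ids: list[str]
    map: SnpMap
    alleles: np.ndarray  # (nanim, nsnp, 2) uint8

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (nanim, nsnp, 2)")
        if self.alleles.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length does not match allele array")
        if self.alleles.shape[1] != self.map.n_snp:
            raise ValueError("map length does not match allele array")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        if self.alleles.size and self.alleles.max() > 1:
            raise GenotypeFormatError("alleles must be 0/1")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> np.ndarray:
        """0/1/2 alternative-allele counts, shape (nanim, nsnp)."""
        return self.alleles.sum(axis=2, dtype=np.int8)

    def subset_animals(self, ids: list[str]) -> "PhasedGenotypes":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"animals not in genotypes: {missing[:5]}")
        rows = [index[a] for a in ids]
        return PhasedGenotypes(list(ids), self.map, self.alleles[rows])


@dataclass
class PhenotypeTable:
    """Per-animal trait records with contemporary group and age covariate."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("animal_id", "trait", "cg", "age", "breed")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if self.frame["animal_id"].duplicated().any():
            dup = self.frame.loc[self.frame["animal_id"].duplicated(), "animal_id"].iloc[0]
            raise ValueError(f"duplicate animal_id {dup!r} in phenotype table")

    @property
    def animal_ids(self) -> list[str]:
        return self.frame["animal_id"].tolist()

    def with_trait(self) -> pd.DataFrame:
        """Rows with an observed trait (prediction-only animals dropped)."""
        return self.frame.loc[self.frame["trait"].notna()].reset_index(drop=True)


@dataclass
class ReferenceLabels:
    """Subspecies (indicus/taurus) and breed labels for the reference panel."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("animal_id", "subspecies", "breed"):
            if col not in self.frame.columns:
                raise ValueError(f"labels missing column {col!r}")
        bad = set(self.frame["subspecies"]) - {"indicus", "taurus"}
        if bad:
            raise ValueError(f"unknown subspecies labels: {sorted(bad)}")

    def validate_against(self, g: PhasedGenotypes) -> None:
        missing = set(self.frame["animal_id"]) - set(g.animal_ids)
        if missing:
            raise ValueError(f"labelled animals absent from genotypes: {sorted(missing)[:5]}")
        present = set(self.frame["subspecies"])
        if present != {"indicus", "taurus"}:
            raise ValueError("both subspecies must be represented in the reference panel")

    def ids_for(self, subspecies: str) -> list[str]:
        f = self.frame
        return f.loc[f["subspecies"] == subspecies, "animal_id"].tolist()


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path: str, require_phased: bool = True) -> PhasedGenotypes:
    """Read a bi-allelic phased VCF into a :class:`PhasedGenotypes`.

    Parameters
    ----------
    path
        Plain-text or bgzipped VCF. Every record must be bi-allelic with
        complete GT fields; ``0|1``-style phased calls are required unless
        ``require_phased`` is False (``0/1`` then contributes its allele sum
        with an arbitrary but deterministic phase: lower allele first).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    animal_ids = list(vcf.samples)
    snp_id, chrom, pos, ref, alt = [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeFormatError(
                f"multi-allelic site at {rec.CHROM}:{rec.POS} ({rec.ID or '.'})"
            )
        gts = rec.genotypes  # [a0, a1, phased]
        site = np.empty((len(animal_ids), 2), dtype=np.int16)
        for i, (a0, a1, phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                raise GenotypeFormatError(
                    f"missing genotype for sample {animal_ids[i]} at {rec.CHROM}:{rec.POS}"
                )
            if require_phased and not phased:
                raise GenotypeFormatError(
                    f"unphased genotype for sample {animal_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS} ({rec.ID or '.'})"
                )
            if not phased and a0 > a1:
                a0, a1 = a1, a0
            site[i, 0], site[i, 1] = a0, a1
        rows.append(site)
        snp_id.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    if not rows:
        raise GenotypeFormatError("VCF contains no records")
    alleles = np.stack(rows, axis=1).astype(np.uint8)
    smap = SnpMap(
        snp_id=np.array(snp_id, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
    )
    return PhasedGenotypes(animal_ids, smap, alleles)


def write_phased_vcf(g: PhasedGenotypes, path: str) -> None:
    """Write a minimal phased VCF v4.2 (text, uncompressed)."""
    m = g.map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(np.asarray(m.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.animal_ids)
            + "\n"
        )
        a = g.alleles
        for j in range(g.n_snp):
            gts = "\t".join(f"{a[i, j, 0]}|{a[i, j, 1]}" for i in range(g.n_animals))
            fh.write(
                f"{m.chrom[j]}\t{m.pos_bp[j]}\t{m.snp_id[j]}\t{m.ref_allele[j]}\t"
                f"{m.alt_allele[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Haplotype TSV dialect


def write_haplotype_tsv(g: PhasedGenotypes, path: str) -> None:
    """Write the haplotype TSV dialect.

    One row per haplotype copy: columns ``animal_id``, ``copy`` (0/1), then
    one 0/1 column per SNP named by snp_id, in map order. ``#``-prefixed
    header lines carry the map (chrom, pos, ref, alt per SNP).
    """
    m = g.map
    with open(path, "w") as fh:
        fh.write("#boamap-haplotypes v1\n")
        fh.write("#snp_id\t" + "\t".join(map(str, m.snp_id)) + "\n")
        fh.write("#chrom\t" + "\t".join(map(str, m.chrom)) + "\n")
        fh.write("#pos_bp\t" + "\t".join(map(str, m.pos_bp)) + "\n")
        fh.write("#ref\t" + "\t".join(map(str, m.ref_allele)) + "\n")
        fh.write("#alt\t" + "\t".join(map(str, m.alt_allele)) + "\n")
        fh.write("animal_id\tcopy\t" + "\t".join(map(str, m.snp_id)) + "\n")
        for i, aid in enumerate(g.animal_ids):
            for c in (0, 1):
                row = "\t".join(map(str, g.alleles[i, :, c]))
                fh.write(f"{aid}\t{c}\t{row}\n")


def read_haplotype_tsv(path: str) -> PhasedGenotypes:
    """Read the dialect written by :func:`write_haplotype_tsv` (lossless)."""
    meta: dict[str, list[str]] = {}
    body: list[tuple[str, int, list[str]]] = []
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if len(parts) > 1:
                    meta[parts[0]] = parts[1:]
                continue
            parts = line.split("\t")
            if header_cols is None:
                header_cols = parts
                continue
            if len(parts) != len(header_cols):
                raise GenotypeFormatError(f"ragged row at line {lineno}")
            body.append((parts[0], int(parts[1]), parts[2:]))
    if header_cols is None or not body:
        raise GenotypeFormatError("no haplotypes in file")
    for key in ("snp_id", "chrom", "pos_bp", "ref", "alt"):
        if key not in meta:
            raise GenotypeFormatError(f"missing #{key} header line")
    nsnp = len(meta["snp_id"])
    if len(body) % 2:
        raise GenotypeFormatError("odd number of haplotype rows")
    animal_ids: list[str] = []
    alleles = np.empty((len(body) // 2, nsnp, 2), dtype=np.uint8)
    for k in range(0, len(body), 2):
        (aid0, c0, row0), (aid1, c1, row1) = body[k], body[k + 1]
        if aid0 != aid1 or {c0, c1} != {0, 1}:
            raise GenotypeFormatError(f"haplotype rows for {aid0!r} not paired 0/1")
        animal_ids.append(aid0)
        for c, row in ((c0, row0), (c1, row1)):
            vals = np.array(row)
            if not np.isin(vals, ["0", "1"]).all():
                bad = vals[~np.isin(vals, ["0", "1"])][0]
                raise GenotypeFormatError(f"allele {bad!r} outside {{0,1}} for {aid0!r}")
            alleles[k // 2, :, c] = vals.astype(np.uint8)
    smap = SnpMap(
        snp_id=np.array(meta["snp_id"], dtype=object),
        chrom=np.array(meta["chrom"], dtype=object),
        pos_bp=np.array(meta["pos_bp"], dtype=np.int64),
        ref_allele=np.array(meta["ref"], dtype=object),
        alt_allele=np.array(meta["alt"], dtype=object),
    )
    return PhasedGenotypes(animal_ids, smap, alleles)


# ---------------------------------------------------------------------------
# Phenotypes and labels


def read_phenotypes(path: str, rms_range_check: bool = True) -> PhenotypeTable:
    """Read the phenotype TSV (animal_id, trait, cg, age, breed).

    Empty trait fields mark prediction-only animals. With
    ``rms_range_check`` a trait outside the 0-5 reproductive-maturity-score
    scale raises a warning (not an error: other traits may reuse the column).
    """
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    tab = {}
    tab["animal_id"] = df["animal_id"]
    for col, required in (("trait", False), ("age", True)):
        vals = []
        for row, s in enumerate(df[col], start=2):
            if s == "" and not required:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(s))
            except ValueError:
                raise ValueError(f"non-numeric {col} {s!r} at line {row} of {path}") from None
        tab[col] = vals
    tab["cg"] = df["cg"].astype("category")
    tab["breed"] = df["breed"].astype("category")
    out = pd.DataFrame(tab)[list(PhenotypeTable.REQUIRED)]
    if rms_range_check:
        t = out["trait"].dropna()
        if len(t) and ((t < 0) | (t > 5)).any():
            warnings.warn("trait values outside the 0-5 RMS scale", stacklevel=2)
    return PhenotypeTable(out)


def read_reference_labels(path: str) -> ReferenceLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    return ReferenceLabels(df)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a data frame as TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)


def check_shared_reference(a: SnpMap, b: SnpMap) -> None:
    """Require two maps to agree on REF/ALT orientation per snp_id.

    Reference and target files must be expressed against the same arbitrary
    reference-allele orientation; re-referencing is upstream of this package.
    """
    if a.n_snp != b.n_snp or not np.array_equal(a.snp_id, b.snp_id):
        raise ValueError("reference and target SNP sets differ")
    same = np.array_equal(a.ref_allele, b.ref_allele) and np.array_equal(
        a.alt_allele, b.alt_allele
    )
    if not same:
        raise ValueError("REF/ALT orientation differs between reference and target files")
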