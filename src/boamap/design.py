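"""Origin-partitioned and control design matrices.

For each SNP j the origin matrix carries three columns (3j, 3j+1, 3j+2) for
the Bi / Bt / Bx diplotype class of the SNP's window; an animal's 0/1/2
dosage at that SNP is written to exactly one of the three, so the matrix is
nanim x 3nsnp with at least two structural zeros per SNP per animal. The
Bx column takes the whole dosage of heterozygous-origin windows, which is
what lets its effect capture the indicus x taurus (heterosis) contrast.
The control matrix is the plain nanim x nsnp dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import PhasedGenotypes
from .origin import OriginCalls
from .windows import WindowSet

CLASSES = ("Bi", "Bt", "Bx")
_CLASS_OFFSET = {"Bi": 0, "Bt": 1, "Bx": 2}


def column_key(snp_index: int, cls: str) -> int:
    """Column index of (SNP j, origin class) in the origin matrix."""
    return 3 * snp_index + _CLASS_OFFSET[cls]


def column_key_inverse(col: int) -> tuple[int, str]:
    return col // 3, CLASSES[col % 3]


@dataclass
class OriginDesignMatrix:
    """Sparse nanim x 3nsnp dosage matrix partitioned by origin class."""

    animal_ids: list[str]
    snp_ids: np.ndarray
    X: sp.csc_matrix

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def column_labels(self) -> pd.DataFrame:
        snp = np.repeat(self.snp_ids, 3)
        cls = np.tile(np.array(CLASSES, dtype=object), self.n_snp)
        return pd.DataFrame({"snp_id": snp, "class": cls})

    def collapse(self) -> np.ndarray:
        """Sum each SNP's three class columns back to a dense dosage matrix."""
        dense = np.asarray(self.X.todense())
        return dense.reshape(len(self.animal_ids), self.n_snp, 3).sum(axis=2)


@dataclass
class ControlDesignMatrix:
    """Dense nanim x nsnp dosage (0/1/2) matrix, no origin adjustment."""

    animal_ids: list[str]
    snp_ids: np.ndarray
    X: np.ndarray

    def column_labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "class": np.repeat("control", len(self.snp_ids))}
        )


def build_control_xmatrix(g: PhasedGenotypes) -> ControlDesignMatrix:
    return ControlDesignMatrix(
        animal_ids=list(g.animal_ids),
        snp_ids=np.asarray(g.map.snp_id),
        X=g.dosages().astype(np.float64),
    )


def build_origin_xmatrix(
    g: PhasedGenotypes, calls: OriginCalls, ws: WindowSet
) -> OriginDesignMatrix:
    """Expand dosages into the origin-partitioned matrix.

    Every SNP inherits the diplotype class of its window; the animal's
    dosage lands in that class's column and the other two stay zero, so
    collapsing the three columns per SNP recovers the control matrix.
    """
    if calls.window_set.n_windows != ws.n_windows:
        raise ValueError("origin calls do not cover the window set")
    if g.n_animals != calls.n_animals:
        raise ValueError("genotypes and origin calls disagree on animals")
    dos = g.dosages()
    win_of_snp = ws.snp_window_index()
    # class offset per (animal, window): Bi->0, Bt->1, Bx->2
    s = calls.hap_origin.sum(axis=2)  # 2=Bi, 0=Bt, 1=Bx
    offset_by_window = np.where(s == 2, 0, np.where(s == 0, 1, 2))
    offsets = offset_by_window[:, win_of_snp]  # (nanim, nsnp)
    rows, cols_j = np.nonzero(dos)
    data = dos[rows, cols_j].astype(np.float64)
    cols = 3 * cols_j + offsets[rows, cols_j]
    X = sp.csc_matrix(
        (data, (rows, cols)), shape=(g.n_animals, 3 * g.n_snp), dtype=np.float64
    )
    return OriginDesignMatrix(
        animal_ids=list(g.animal_ids), snp_ids=np.asarray(g.map.snp_id), X=X
    )


def write_origin_matrix(m: OriginDesignMatrix, mtx_path: str, labels_path: str) -> None:
    """Serialise as MatrixMarket triplets plus a column-label TSV sidecar."""
    import scipy.io as sio

    from .io import write_tsv

    sio.mmwrite(mtx_path, m.X)
    write_tsv(m.column_labels(), labels_path)


def read_origin_matrix(
    mtx_path: str, labels_path: str, animal_ids: list[str]
) -> OriginDesignMatrix:
    import scipy.io as sio

    from .io import read_tsv

    X = sp.csc_matrix(sio.mmread(mtx_path))
    labels = read_tsv(labels_path)
    snp_ids = labels["snp_id"].to_numpy(dtype=object)[::3]
    return OriginDesignMatrix(animal_ids=list(animal_ids), snp_ids=snp_ids, X=X)
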