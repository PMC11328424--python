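"""Cross-modality alignment scoring: FOSCTTM.

Given two embeddings of the same cells in one integrated space (e.g. RNA
and ATAC profiles of a multiome experiment), the Fraction Of Samples
Closer Than the True Match asks, for each cell, how many cells of the
other modality sit closer (in cosine distance) than the cell's own
profile.  0 means every cell's true match is its nearest neighbor;
independent embeddings score 0.5 on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import FormatError

__all__ = ["PairedEmbeddings", "foscttm"]


@dataclass
class PairedEmbeddings:
    """Row-aligned embeddings of the same cells from two modalities."""

    X1: np.ndarray
    X2: np.ndarray
    cell_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape != self.X2.shape or self.X1.ndim != 2:
            raise FormatError("X1 and X2 must be matrices of identical shape")
        if self.X1.shape[0] < 2:
            raise FormatError("need at least 2 cells")
        for name, X in (("X1", self.X1), ("X2", self.X2)):
            if np.any(np.linalg.norm(X, axis=1) == 0):
                raise FormatError(f"{name} has an all-zero row: cosine undefined")

    @property
    def n(self) -> int:
        return self.X1.shape[0]


def foscttm(pair: PairedEmbeddings) -> tuple[np.ndarray, float]:
    """Fraction of samples closer than the true match, per cell and mean.

    d is the cosine distance between rows of X1 and X2.  For cell i,
    R_i counts the cells j with d_ij ≤ d_ii (ties count against the
    match), and frac_i = (R_i − 1)/(n − 1); the two directions (X1→X2 and
    X2→X1) are averaged per cell.
    """
    D = cdist(pair.X1, pair.X2, metric="cosine")
    d_true = np.diag(D)
    n = pair.n
    # rows: X1[i] against all X2; columns: X2[i] against all X1
    r_fwd = (D <= d_true[:, None]).sum(axis=1)
    r_rev = (D <= d_true[None, :]).sum(axis=0)
    per_cell = ((r_fwd - 1) + (r_rev - 1)) / (2.0 * (n - 1))
    return per_cell, float(per_cell.mean())
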