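"""kNN and shared-nearest-neighbor graph construction from embeddings.

The SNN graph is the substrate for graph-level metrics and graph-based
clustering: edge weight between two cells is the Jaccard overlap of their
k-nearest-neighbor sets (each set including the cell itself), with weights
at or below a prune threshold removed.  Neighbor search is exact; distance
ties are broken by ascending cell index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .io_core import EmbeddingMatrix, NeighborGraph, ParameterError

__all__ = ["KnnSpec", "knn_indices", "knn_distances", "build_knn", "build_snn"]

_CHUNK = 512  # rows per distance block; caps memory at n*_CHUNK floats


@dataclass(frozen=True)
class KnnSpec:
    """Neighbor-search settings: k neighbors per cell, euclidean or cosine."""

    k: int = 20
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.metric not in ("euclidean", "cosine"):
            raise ParameterError(f"unsupported metric {self.metric!r}")


def knn_indices(
    embedding: EmbeddingMatrix,
    k: int,
    metric: str = "euclidean",
    include_self: bool = False,
) -> np.ndarray:
    """Exact k-nearest-neighbor indices, (n, k) integer array.

    With ``include_self`` the cell itself is the first entry and only k−1
    other cells follow (the Seurat SNN convention); otherwise the k nearest
    *other* cells are returned.  Ties broken by ascending cell index
    (stable sort on the distance row).
    """
    X = embedding.coords
    n = X.shape[0]
    if not (1 <= k < n + int(include_self)):
        raise ParameterError(f"k={k} out of range for n={n}")
    n_other = k - 1 if include_self else k
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        D = cdist(X[start:stop], X, metric=metric)
        rows = np.arange(start, stop)
        D[np.arange(stop - start), rows] = np.inf  # exclude self from "others"
        order = np.argsort(D, axis=1, kind="stable")[:, :n_other]
        if include_self:
            out[start:stop, 0] = rows
            out[start:stop, 1:] = order
        else:
            out[start:stop] = order
    return out


def knn_distances(
    embedding: EmbeddingMatrix, k: int, metric: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """(indices, distances) of the k nearest other cells, both (n, k)."""
    idx = knn_indices(embedding, k, metric=metric, include_self=False)
    X = embedding.coords
    n = X.shape[0]
    dist = np.empty_like(idx, dtype=float)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        D = cdist(X[start:stop], X, metric=metric)
        dist[start:stop] = np.take_along_axis(D, idx[start:stop], axis=1)
    return idx, dist


def build_knn(embedding: EmbeddingMatrix, spec: KnnSpec = KnnSpec()) -> NeighborGraph:
    """Unweighted kNN graph: directed k-neighbor lists symmetrized by union."""
    idx = knn_indices(embedding, spec.k, metric=spec.metric, include_self=False)
    n = embedding.n
    rows = np.repeat(np.arange(n), spec.k)
    A = sp.coo_matrix((np.ones(n * spec.k), (rows, idx.ravel())), shape=(n, n))
    A = A.maximum(A.T)  # union of directed edges
    A.setdiag(0)
    return NeighborGraph(embedding.cell_ids, sp.csr_matrix(A), kind="knn")


def build_snn(
    embedding: EmbeddingMatrix,
    k: int = 20,
    prune: float = 1 / 15,
    metric: str = "euclidean",
) -> NeighborGraph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    weight(i, j) = |N(i) ∩ N(j)| / |N(i) ∪ N(j)| where N(·) is the set of
    the k nearest cells including the cell itself.  Weights ≤ ``prune`` are
    set to zero (default 1/15, the Seurat convention).
    """
    if not 0 <= prune < 1:
        raise ParameterError("prune must be in [0, 1)")
    idx = knn_indices(embedding, k, metric=metric, include_self=True)
    n = embedding.n
    # membership matrix M[i, c] = 1 iff c in N(i); |N(i)| = k for all i
    rows = np.repeat(np.arange(n), k)
    M = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (M @ M.T).tocoo()
    union = 2.0 * k - inter.data
    w = inter.data / union
    keep = w > prune
    A = sp.coo_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    A = sp.csr_matrix(A)
    A.setdiag(0)
    A.eliminate_zeros()
    return NeighborGraph(embedding.cell_ids, A, kind="snn")
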