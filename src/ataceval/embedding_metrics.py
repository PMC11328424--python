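"""Embedding-level evaluation: silhouette widths (ASW, FNS) and cLISI.

ASW is the classic average silhouette width; since raw silhouettes are not
invariant to rescaling of the latent space across methods, the fraction of
negative silhouettes per class (FNS) is reported alongside as a
scale-robust summary.  cLISI — the cluster-level Local Inverse Simpson
Index — measures the effective number of classes in each cell's
kernel-weighted neighborhood: 1 means every neighborhood is pure, K means
classes are completely mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from .graphs import knn_distances
from .io_core import EmbeddingMatrix, LabelVector, ParameterError

logger = logging.getLogger("ataceval")

__all__ = ["SilhouetteResult", "LisiResult", "silhouette", "clisi"]


@dataclass
class SilhouetteResult:
    per_cell: np.ndarray
    asw_per_class: dict[str, float]
    fns_per_class: dict[str, float]
    asw_mean: float
    fns_mean: float


@dataclass
class LisiResult:
    per_cell: np.ndarray
    mean: float
    perplexity: float
    k_neighbors: int


def silhouette(
    embedding: EmbeddingMatrix,
    labels: LabelVector,
    metric: str = "euclidean",
) -> SilhouetteResult:
    """Per-cell silhouettes with per-class ASW and FNS summaries.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)), a = mean intra-class distance
    (self excluded), b = smallest mean distance to another class.  Cells in
    singleton classes get s = 0.  ASW and FNS are averaged per class and
    then averaged over classes with equal weight.
    """
    if metric != "euclidean":
        raise ParameterError("only euclidean distance is supported")
    if labels.K < 2:
        raise ParameterError("silhouette undefined for a single class")
    codes = labels.codes()
    s = silhouette_samples(embedding.coords, codes, metric=metric)
    asw_pc: dict[str, float] = {}
    fns_pc: dict[str, float] = {}
    for j, cls in enumerate(labels.classes):
        mask = codes == j
        asw_pc[cls] = float(s[mask].mean())
        fns_pc[cls] = float((s[mask] < 0).mean())
    return SilhouetteResult(
        per_cell=s,
        asw_per_class=asw_pc,
        fns_per_class=fns_pc,
        asw_mean=float(np.mean(list(asw_pc.values()))),
        fns_mean=float(np.mean(list(fns_pc.values()))),
    )


def _calibrated_weights(
    dist: np.ndarray, perplexity: float, max_iter: int = 100, tol: float = 1e-5
) -> np.ndarray:
    """Per-row Gaussian kernel weights with entropy = log(perplexity).

    For each cell, weights w_j ∝ exp(−β d_j²) over its neighbors; β is
    found by bisection so that the Shannon entropy of the normalized
    weights matches log(perplexity).  Rows that fail to converge fall back
    to uniform weights (logged).
    """
    n, k = dist.shape
    target = np.log(perplexity)
    d2 = dist**2
    d2 = d2 - d2[:, :1]  # shift by the nearest distance for stability
    beta = np.ones(n)
    lo = np.full(n, -np.inf)
    hi = np.full(n, np.inf)
    W = np.empty_like(d2)
    H = np.empty(n)
    for _ in range(max_iter):
        np.exp(-beta[:, None] * d2, out=W)
        sumW = W.sum(axis=1)
        W /= sumW[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logW = np.where(W > 0, np.log(W), 0.0)
        H = -(W * logW).sum(axis=1)
        diff = H - target
        if np.all(np.abs(diff) < tol):
            break
        too_entropic = diff > 0  # entropy too high -> sharpen -> raise beta
        lo = np.where(too_entropic, beta, lo)
        hi = np.where(~too_entropic, beta, hi)
        beta = np.where(
            too_entropic,
            np.where(np.isinf(hi), beta * 2.0, (beta + hi) / 2.0),
            np.where(np.isinf(lo), beta / 2.0, (beta + lo) / 2.0),
        )
    bad = np.abs(H - target) >= tol
    # degenerate rows (all neighbors at one distance) can never match the
    # target entropy; uniform weights are the correct limit there
    if np.any(bad):
        logger.warning(
            "cLISI bandwidth calibration did not converge for %d cells; "
            "using uniform weights",
            int(bad.sum()),
        )
        W[bad] = 1.0 / k
    return W


def clisi(
    embedding: EmbeddingMatrix,
    labels: LabelVector,
    perplexity: float = 30.0,
    k_neighbors: int = 90,
) -> LisiResult:
    """Cluster-level Local Inverse Simpson Index.

    Per cell: Gaussian weights over its k nearest neighbors are calibrated
    to the given perplexity; class probabilities p(c) sum those weights by
    class; the score is 1 / Σ_c p(c)², bounded in [1, K].
    """
    n = embedding.n
    if k_neighbors >= n:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < n={n}")
    if perplexity >= k_neighbors:
        raise ParameterError("perplexity must be smaller than k_neighbors")
    idx, dist = knn_distances(embedding, k_neighbors)
    W = _calibrated_weights(dist, perplexity)
    codes = labels.codes()
    K = labels.K
    neighbor_codes = codes[idx]  # (n, k)
    simpson = np.zeros(n)
    for c in range(K):
        pc = np.where(neighbor_codes == c, W, 0.0).sum(axis=1)
        simpson += pc**2
    per_cell = 1.0 / simpson
    return LisiResult(
        per_cell=per_cell,
        mean=float(per_cell.mean()),
        perplexity=float(perplexity),
        k_neighbors=int(k_neighbors),
    )
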