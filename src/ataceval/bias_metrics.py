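"""Library-size bias quantification and Geary's C spatial autocorrelation.

Sequencing depth (unique fragments per cell) is a technical covariate;
when it leaks into a latent representation, clusters can reflect depth
rather than biology.  Two complementary measurements are provided: the
within-class Pearson correlation between each latent dimension and the
square root of library size, averaged in absolute value over classes
(depth leakage per component), and Geary's C of a per-cell signal —
conventionally log-transformed fragment counts — on a kNN graph (depth
smoothness over the whole embedding; ≈1 under no autocorrelation, →0 for
perfectly smooth signals).  A simple component filter reproduces the
common practice of dropping latent components whose correlation with raw
depth exceeds a threshold (0.75 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    EmbeddingMatrix,
    LabelVector,
    LibrarySizeVector,
    NeighborGraph,
    ParameterError,
)

logger = logging.getLogger("ataceval")

__all__ = ["BiasResult", "library_size_correlation", "component_filter", "gearys_c"]


@dataclass
class BiasResult:
    per_dimension: dict[int, float]
    summary: float
    removed_components: list[int] = field(default_factory=list)
    gearys_c: float | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt((x**2).sum())
    sy = np.sqrt((y**2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float((x * y).sum() / (sx * sy))


def library_size_correlation(
    embedding: EmbeddingMatrix,
    labels: LabelVector,
    libsize: LibrarySizeVector,
    dims: int | None = None,
) -> BiasResult:
    """Per-dimension depth leakage r_l, averaged within classes.

    For latent dimension l, the Pearson correlation between sqrt(library
    size) and the coordinates is computed within each class and the
    absolute values are averaged over classes.  Classes with fewer than 3
    cells, or with zero variance in either vector, are skipped (logged).
    ``summary`` is the mean over the first min(dims, 5) dimensions.
    """
    if not (embedding.cell_ids == labels.cell_ids == libsize.cell_ids):
        raise ParameterError("inputs not aligned: run align() first")
    dims = embedding.d if dims is None else min(dims, embedding.d)
    root = np.sqrt(libsize.counts.astype(float))
    codes = labels.codes()
    per_dim: dict[int, float] = {}
    for l in range(dims):
        coords = embedding.coords[:, l]
        rs = []
        for c in range(labels.K):
            mask = codes == c
            if mask.sum() < 3:
                logger.warning(
                    "library_size_correlation: class %r has <3 cells; skipped",
                    labels.classes[c],
                )
                continue
            r = _pearson(root[mask], coords[mask])
            if np.isnan(r):
                logger.warning(
                    "library_size_correlation: zero variance in class %r, dim %d",
                    labels.classes[c],
                    l + 1,
                )
                continue
            rs.append(abs(r))
        per_dim[l + 1] = float(np.mean(rs)) if rs else np.nan
    head = [per_dim[l] for l in range(1, min(dims, 5) + 1)]
    summary = float(np.nanmean(head)) if head else np.nan
    return BiasResult(per_dimension=per_dim, summary=summary)


def component_filter(
    embedding: EmbeddingMatrix,
    libsize: LibrarySizeVector,
    threshold: float = 0.75,
) -> tuple[list[int], list[int]]:
    """Drop latent components correlated with raw depth above ``threshold``.

    The correlation is Pearson's r between each dimension and the total
    counts across *all* cells (no class stratification).  Returns
    (kept, removed) 1-based dimension indices, order preserved.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    if embedding.cell_ids != libsize.cell_ids:
        raise ParameterError("inputs not aligned: run align() first")
    counts = libsize.counts.astype(float)
    kept, removed = [], []
    for l in range(embedding.d):
        r = _pearson(counts, embedding.coords[:, l])
        if not np.isnan(r) and abs(r) > threshold:
            removed.append(l + 1)
        else:
            kept.append(l + 1)
    if not kept:
        raise ParameterError("no informative components: all dimensions removed")
    return kept, removed


def gearys_c(graph: NeighborGraph, x: np.ndarray) -> float:
    """Geary's C of a per-cell signal on a neighbor graph.

        C = (N−1)·Σ_ij w_ij (x_i − x_j)² / (2·S₀·Σ_i (x_i − x̄)²)

    with S₀ the sum of all weights (each symmetric edge counted in both
    directions, like the numerator's double sum).  C ≈ 1 for spatially
    unstructured signals, < 1 for smooth ones, 0 when x is constant on
    every connected component.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != graph.n:
        raise ParameterError("x must be a per-cell vector aligned to the graph")
    denom_var = float(((x - x.mean()) ** 2).sum())
    if denom_var == 0:
        raise ParameterError("zero variance: Geary's C undefined")
    A = graph.adjacency.tocoo()
    s0 = float(A.data.sum())
    if s0 == 0:
        raise ParameterError("graph has no edges")
    num = float((A.data * (x[A.row] - x[A.col]) ** 2).sum())
    n = graph.n
    return float((n - 1) * num / (2.0 * s0 * denom_var))
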