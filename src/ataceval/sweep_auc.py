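"""Resolution/seed sweeps, normalized AUC summaries, and seed stability.

Graph-based clustering has no canonical resolution, and the best score is
not always reached at the true number of clusters; partitions are
therefore scored across a grid of resolutions and random seeds, the
metric-versus-cluster-number curve is averaged per cluster number, and
its trapezoidal area — normalized by the metric's upper bound and the
cluster-number range — summarizes each method with one number.  A robust
median-deviation transform puts AUC matrices from different datasets on
one color scale, and seed-to-seed ARI deviations quantify clustering
stability.

Clustering itself is pluggable: partitions come either precomputed or
from a caller-supplied callback (e.g., a Leiden run on an SNN graph);
this module never embeds a community-detection algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_core import LabelVector, ParameterError, Partition
from .partition_metrics import ari, ari2, contingency, mi_vi, wallace_adjusted

logger = logging.getLogger("ataceval")

__all__ = [
    "DEFAULT_RESOLUTIONS",
    "DEFAULT_SEEDS",
    "SweepEntry",
    "SweepGrid",
    "run_sweep",
    "auc_curve",
    "heatmap_transform",
    "stability",
]

DEFAULT_RESOLUTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 21))
DEFAULT_SEEDS: tuple[int, ...] = (0, 2, 5, 42, 123)

#: metric name -> function of a Contingency returning a float
_METRIC_FUNS: dict[str, Callable] = {
    "ari": lambda c: ari(c)[0],
    "ari2": ari2,
    "aw": lambda c: wallace_adjusted(c)[0],
    "av": lambda c: wallace_adjusted(c)[1],
    "mi": lambda c: mi_vi(c)["MI"],
    "vi": lambda c: mi_vi(c)["VI"],
}


@dataclass
class SweepEntry:
    resolution: float
    seed: int
    partition: Partition
    n_clusters: int
    metrics: dict[str, float]


@dataclass
class SweepGrid:
    entries: list[SweepEntry] = field(default_factory=list)
    failures: list[tuple[float, int, str]] = field(default_factory=list)


def run_sweep(
    labels: LabelVector,
    partitions: Mapping[tuple[float, int], Partition] | None = None,
    clusterer: Callable[[float, int], Partition] | None = None,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    metrics: Sequence[str] = ("ari", "ari2", "aw", "av", "mi", "vi"),
) -> SweepGrid:
    """Score partitions over a (resolution, seed) grid against the labels.

    Partitions come either from ``partitions`` (a mapping keyed by
    (resolution, seed)) or from ``clusterer(resolution, seed)``; with a
    callback, entries whose call raises are skipped and the failure
    recorded.  Each scored entry holds the partition, its cluster count,
    and the requested partition-level metrics.
    """
    unknown = set(metrics) - set(_METRIC_FUNS)
    if unknown:
        raise ParameterError(f"unknown metrics: {sorted(unknown)}")
    if partitions is None and clusterer is None:
        raise ParameterError("supply partitions or a clusterer callback")
    if partitions is not None and len(partitions) == 0:
        raise ParameterError("empty partition map")
    grid = SweepGrid()
    keys: Iterable[tuple[float, int]]
    if partitions is not None:
        keys = sorted(partitions.keys())
    else:
        keys = [(r, s) for r in resolutions for s in seeds]
    for res, seed in keys:
        try:
            part = partitions[(res, seed)] if partitions is not None else clusterer(res, seed)
        except Exception as exc:  # callback contract: skip and record
            logger.warning("sweep entry (res=%s, seed=%s) failed: %s", res, seed, exc)
            grid.failures.append((res, seed, str(exc)))
            continue
        c = contingency(labels, part)
        vals = {m: float(_METRIC_FUNS[m](c)) for m in metrics}
        grid.entries.append(
            SweepEntry(float(res), int(seed), part, part.J, vals)
        )
    return grid


def auc_curve(
    grid: SweepGrid,
    metric: str,
    upper_bound: float | str = 1.0,
) -> tuple[dict[int, float], float]:
    """Mean-metric curve over cluster numbers and its normalized AUC.

    Metric values are averaged at each observed cluster number; the
    trapezoidal area over the observed cluster-number range is divided by
    (upper bound × range width).  ``upper_bound`` may be a number or
    ``"empirical_max"`` (the sweep's own maximum — the convention for the
    unbounded MI and VI).  For VI the returned score is 1 − normalized
    AUC, so that higher remains better for every metric.
    """
    vals_by_k: dict[int, list[float]] = {}
    for e in grid.entries:
        if metric not in e.metrics:
            raise ParameterError(f"metric {metric!r} missing from sweep entries")
        vals_by_k.setdefault(e.n_clusters, []).append(e.metrics[metric])
    if len(vals_by_k) < 2:
        raise ParameterError("degenerate range: need >= 2 distinct cluster numbers")
    ks = np.array(sorted(vals_by_k), dtype=float)
    curve = {int(k): float(np.mean(vals_by_k[int(k)])) for k in ks}
    means = np.array([curve[int(k)] for k in ks])
    if upper_bound == "empirical_max":
        ub = float(np.nanmax([e.metrics[metric] for e in grid.entries]))
    else:
        ub = float(upper_bound)
    if ub == 0:
        raise ParameterError("upper bound is 0: normalized AUC undefined")
    area = float(np.trapezoid(means, ks))
    norm = area / (ub * (ks[-1] - ks[0]))
    if metric == "vi":
        norm = 1.0 - norm
    return curve, float(norm)


def heatmap_transform(A: np.ndarray) -> np.ndarray:
    """Robust rescaling of a methods × metrics AUC matrix.

    Each column is centered on its median; the centered matrix is divided
    by the median of all absolute deviations (one scalar for the whole
    matrix), so color scales are comparable across datasets and robust to
    outliers.  A constant matrix maps to all zeros.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(A)):
        raise ParameterError("matrix must be finite")
    M = A - np.median(A, axis=0, keepdims=True)
    scale = float(np.median(np.abs(M)))
    if scale == 0:
        logger.warning("heatmap_transform: zero median absolute deviation; returning zeros")
        return np.zeros_like(M)
    return M / scale


def stability(grid: SweepGrid) -> tuple[dict[float, float], float]:
    """Seed-to-seed clustering robustness.

    Per resolution, every pair of seeds is compared by the ARI between
    their two predicted partitions (ground truth plays no role) and the
    deviation 1 − ARI is averaged over pairs; the overall value averages
    over resolutions.  0 means seeds always agree up to relabeling;
    chance-level agreement gives values near 1.  Resolutions with a single
    seed are excluded.
    """
    by_res: dict[float, list[SweepEntry]] = {}
    for e in grid.entries:
        by_res.setdefault(e.resolution, []).append(e)
    per_resolution: dict[float, float] = {}
    for res, entries in sorted(by_res.items()):
        if len(entries) < 2:
            logger.warning("stability: resolution %s has a single seed; excluded", res)
            continue
        devs = []
        for a in range(len(entries)):
            for b in range(a + 1, len(entries)):
                c = contingency(entries[a].partition, entries[b].partition)
                devs.append(1.0 - ari(c)[0])
        per_resolution[res] = float(np.mean(devs))
    overall = float(np.mean(list(per_resolution.values()))) if per_resolution else np.nan
    return per_resolution, overall
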