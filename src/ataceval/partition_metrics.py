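"""Partition-level evaluation: adjusted Wallace indices, ARI, ARI2, MI, VI.

Two partitions of the same cells — ground-truth classes U = {U_1,…,U_I}
and predicted clusters Z = {Z_1,…,Z_J} — are compared through their I × J
contingency table.  The two Wallace indices (the fraction of same-class
object pairs also co-clustered, and vice versa) are adjusted for chance
under the generalized hypergeometric model,

    AS = (S − E[S]) / (1 − E[S]),

giving AW (completeness of classes) and AV (homogeneity of clusters),
each decomposable per class (AW_i) and per cluster (AV_j).  ARI is the
harmonic mean of AW and AV; ARI2 replaces the pair-count weighting with
unweighted means of the decompositions so that rare classes count as much
as abundant ones.  MI and VI are the information-theoretic counterparts
(natural logarithms throughout).

Undefined quantities (zero denominators, e.g. a singleton class's AW_i)
are returned as NaN rather than raising; report serialization turns NaN
into JSON null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.cluster import contingency_matrix

from .io_core import LabelVector, ParameterError, Partition

logger = logging.getLogger("ataceval")

__all__ = [
    "Contingency",
    "PartitionScores",
    "contingency",
    "wallace_adjusted",
    "ari",
    "ari2",
    "mi_vi",
    "evenness",
    "score_partition",
]


def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    return np.asarray(x, dtype=float) * (np.asarray(x, dtype=float) - 1) / 2.0


@dataclass
class Contingency:
    """I × J contingency table with all derived pair counts.

    N is the number of object pairs n(n−1)/2; P and Q count pairs joined
    in U and in Z respectively, with per-class (P_i) and per-cluster (Q_j)
    components.
    """

    n_ij: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.n_ij = np.asarray(self.n_ij, dtype=np.int64)
        self.n_i_plus = self.n_ij.sum(axis=1)
        self.n_plus_j = self.n_ij.sum(axis=0)
        self.n = int(self.n_ij.sum())
        if self.n < 2:
            raise ParameterError("contingency needs n >= 2 (no object pairs)")
        self.N = float(_comb2(self.n))
        self.P_i = _comb2(self.n_i_plus)
        self.Q_j = _comb2(self.n_plus_j)
        self.P = float(self.P_i.sum())
        self.Q = float(self.Q_j.sum())
        self.T = float(_comb2(self.n_ij).sum())  # pairs joined in both
        self.T_i = _comb2(self.n_ij).sum(axis=1)  # per class
        self.T_j = _comb2(self.n_ij).sum(axis=0)  # per cluster
        self.p_ij = self.n_ij / self.n
        self.p_i = self.n_i_plus / self.n
        self.p_j = self.n_plus_j / self.n

    @property
    def I(self) -> int:
        return self.n_ij.shape[0]

    @property
    def J(self) -> int:
        return self.n_ij.shape[1]


def contingency(labels: LabelVector, partition: Partition) -> Contingency:
    """Tabulate ground-truth classes against predicted clusters."""
    if labels.cell_ids != partition.cell_ids:
        raise ParameterError("inputs not aligned: run align() first")
    M = contingency_matrix(labels.codes(), partition.codes())
    return Contingency(M, labels.classes, partition.classes)


# ---------------------------------------------------------------------------
# Pair-counting statistics
# ---------------------------------------------------------------------------


def wallace_adjusted(
    c: Contingency,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Chance-adjusted Wallace indices with their decompositions.

    Returns (AW, AV, AW_i, AV_j).  AW_i is NaN for singleton classes
    (P_i = 0), AV_j likewise for singleton clusters; global AW is NaN when
    Z is trivial (Q = N, e.g. one cluster) and AV when U is trivial.
    """
    N, P, Q, T = c.N, c.P, c.Q, c.T
    with np.errstate(divide="ignore", invalid="ignore"):
        aw = (N * T - P * Q) / (P * (N - Q)) if P > 0 and N > Q else np.nan
        av = (N * T - P * Q) / (Q * (N - P)) if Q > 0 and N > P else np.nan
        aw_i = np.where(
            (c.P_i > 0) & (N > Q),
            (N * c.T_i - c.P_i * Q) / (c.P_i * (N - Q)),
            np.nan,
        )
        av_j = np.where(
            (c.Q_j > 0) & (N > P),
            (N * c.T_j - c.Q_j * P) / (c.Q_j * (N - P)),
            np.nan,
        )
    return float(aw), float(av), aw_i, av_j


def ari(c: Contingency) -> tuple[float, float]:
    """Adjusted Rand index via two equivalent routes.

    First route: the harmonic mean of AW and AV.  Second route: the
    weighted average of the per-class and per-cluster decompositions,

        ARI = (Σ_i AW_i·P_i(N−Q) + Σ_j AV_j·Q_j(N−P))
              / (Σ_i P_i(N−Q) + Σ_j Q_j(N−P)),

    with undefined terms (P_i = 0 or Q_j = 0) contributing zero weight.
    The two agree to machine precision; both are returned.
    """
    aw, av, aw_i, av_j = wallace_adjusted(c)
    N, P, Q, T = c.N, c.P, c.Q, c.T
    if np.isnan(aw) and np.isnan(av):
        return np.nan, np.nan
    # harmonic mean 2·AW·AV/(AW+AV) simplifies to the closed form below
    # (AW and AV share the numerator N·T − P·Q), which also covers the
    # one-sided degenerate limits (e.g. a single predicted cluster)
    denom_h = P * (N - Q) + Q * (N - P)
    harmonic = 2.0 * (N * T - P * Q) / denom_h if denom_h > 0 else np.nan
    w_i = np.where(np.isnan(aw_i), 0.0, c.P_i * (N - Q))
    w_j = np.where(np.isnan(av_j), 0.0, c.Q_j * (N - P))
    denom = w_i.sum() + w_j.sum()
    if denom == 0:
        weighted = np.nan
    else:
        num = (np.nan_to_num(aw_i) * w_i).sum() + (np.nan_to_num(av_j) * w_j).sum()
        weighted = num / denom
    return float(harmonic), float(weighted)


def ari2(c: Contingency) -> float:
    """Class-size-debiased ARI: harmonic mean of the unweighted means
    AW′ = mean_i AW_i and AV′ = mean_j AV_j.

    Singleton classes/clusters (undefined components) are excluded from
    the means with a logged warning.
    """
    _, _, aw_i, av_j = wallace_adjusted(c)
    n_undef = int(np.isnan(aw_i).sum() + np.isnan(av_j).sum())
    if n_undef:
        logger.warning(
            "ari2: excluding %d singleton class/cluster components", n_undef
        )
    if np.all(np.isnan(aw_i)) or np.all(np.isnan(av_j)):
        return np.nan
    aw_p = float(np.nanmean(aw_i))
    av_p = float(np.nanmean(av_j))
    if aw_p + av_p == 0:
        return 0.0 if aw_p == av_p == 0 else np.nan
    return float(2.0 * aw_p * av_p / (aw_p + av_p))


# ---------------------------------------------------------------------------
# Information-theoretic statistics
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0·log 0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def mi_vi(c: Contingency) -> dict[str, float]:
    """Mutual information and variation of information (nats).

    Returns MI, VI, the marginal entropies H_U and H_Z, and the conditional
    entropies H_U_given_Z and H_Z_given_U.  The direct definition
    MI = Σ p_ij log(p_ij / p_i p_j) and the entropy identity
    MI = H(Z) − H(Z|U) agree to machine precision, likewise the two VI
    routes VI = H(U) + H(Z) − 2MI and VI = H(U|Z) + H(Z|U).
    """
    p_ij, p_i, p_j = c.p_ij, c.p_i, c.p_j
    nz = p_ij > 0
    outer = np.outer(p_i, p_j)
    mi = float((p_ij[nz] * np.log(p_ij[nz] / outer[nz])).sum())
    h_u = _entropy(p_i)
    h_z = _entropy(p_j)
    h_uz = _entropy(p_ij.ravel())  # joint entropy
    h_u_given_z = h_uz - h_z
    h_z_given_u = h_uz - h_u
    vi = h_u_given_z + h_z_given_u
    return {
        "MI": mi,
        "VI": vi,
        "H_U": h_u,
        "H_Z": h_z,
        "H_U_given_Z": h_u_given_z,
        "H_Z_given_U": h_z_given_u,
    }


def evenness(labels: LabelVector) -> float:
    """Class-balance index E = exp(H(U)) / K ∈ [1/K, 1]."""
    codes = labels.codes()
    counts = np.bincount(codes)
    p = counts / counts.sum()
    return float(np.exp(_entropy(p)) / labels.K)


# ---------------------------------------------------------------------------
# Bundled scoring
# ---------------------------------------------------------------------------


@dataclass
class PartitionScores:
    AW: float
    AV: float
    ARI: float
    ARI2: float
    AW_prime: float
    AV_prime: float
    AW_i: dict[str, float]
    AV_j: dict[str, float]
    MI: float
    VI: float
    evenness: float


def score_partition(labels: LabelVector, partition: Partition) -> PartitionScores:
    """All partition-level scores for one (labels, prediction) pair."""
    c = contingency(labels, partition)
    aw, av, aw_i, av_j = wallace_adjusted(c)
    ari_h, ari_w = ari(c)
    if np.isfinite(ari_h) and np.isfinite(ari_w) and abs(ari_h - ari_w) > 1e-9:
        logger.warning("ARI routes disagree: %r vs %r", ari_h, ari_w)
    info = mi_vi(c)
    aw_p = float(np.nanmean(aw_i)) if not np.all(np.isnan(aw_i)) else np.nan
    av_p = float(np.nanmean(av_j)) if not np.all(np.isnan(av_j)) else np.nan
    return PartitionScores(
        AW=aw,
        AV=av,
        ARI=ari_h,
        ARI2=ari2(c),
        AW_prime=aw_p,
        AV_prime=av_p,
        AW_i={cls: float(v) for cls, v in zip(c.row_labels, aw_i)},
        AV_j={cl: float(v) for cl, v in zip(c.col_labels, av_j)},
        MI=info["MI"],
        VI=info["VI"],
        evenness=evenness(labels),
    )
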