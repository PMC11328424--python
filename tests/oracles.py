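"""Independent brute-force oracles used to validate the closed forms.

Everything here works from first principles — explicit enumeration of
object pairs, per-node degree splitting, exhaustive pairwise distances —
and never calls the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_pair_stats(u: np.ndarray, z: np.ndarray) -> dict:
    """Pair-counting statistics by enumerating all C(n,2) object pairs.

    The chance adjustment AS = (S − E[S])/(1 − E[S]) uses the
    hypergeometric expectations E[W] = Q/N and E[V] = P/N (and Q·P_i/N
    per class, P·Q_j/N per cluster).
    """
    u = np.asarray(u)
    z = np.asarray(z)
    n = len(u)
    iu = np.triu_indices(n, k=1)
    same_u = (u[:, None] == u[None, :])[iu]
    same_z = (z[:, None] == z[None, :])[iu]
    N = n * (n - 1) / 2
    a = float((same_u & same_z).sum())
    P = float(same_u.sum())
    Q = float(same_z.sum())

    def adjust(s_num, s_den, e_num, e_den):
        # (S − E)/(1 − E) with S = s_num/s_den, E = e_num/e_den
        if s_den == 0 or e_den == e_num:
            return np.nan
        s = s_num / s_den
        e = e_num / e_den
        return (s - e) / (1 - e)

    aw = adjust(a, P, Q, N)
    av = adjust(a, Q, P, N)
    rand_exp = P * Q / N
    denom = (P + Q) / 2 - rand_exp
    ari = (a - rand_exp) / denom if denom != 0 else np.nan

    aw_i = {}
    for cls in dict.fromkeys(u.tolist()):
        mask = (u[iu[0]] == cls) & (u[iu[1]] == cls)
        p_i = float(mask.sum())
        a_i = float((mask & same_z).sum())
        aw_i[cls] = adjust(a_i, p_i, Q, N)
    av_j = {}
    for cl in dict.fromkeys(z.tolist()):
        mask = (z[iu[0]] == cl) & (z[iu[1]] == cl)
        q_j = float(mask.sum())
        a_j = float((mask & same_u).sum())
        av_j[cl] = adjust(a_j, q_j, P, N)

    aw_vals = np.array(list(aw_i.values()), dtype=float)
    av_vals = np.array(list(av_j.values()), dtype=float)
    if np.all(np.isnan(aw_vals)) or np.all(np.isnan(av_vals)):
        ari2 = np.nan
    else:
        awp = np.nanmean(aw_vals)
        avp = np.nanmean(av_vals)
        ari2 = 2 * awp * avp / (awp + avp) if awp + avp != 0 else 0.0
    return {
        "N": N, "P": P, "Q": Q, "pairs_both": a,
        "AW": aw, "AV": av, "AW_i": aw_i, "AV_j": av_j,
        "ARI": ari, "ARI2": ari2,
    }


def brute_silhouette(X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """O(n²) per-cell silhouette; singleton-class cells get 0."""
    n = len(codes)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = (codes == codes[i])
        if own.sum() == 1:
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, codes == c].mean() for c in set(codes.tolist()) if c != codes[i]
        )
        s[i] = (b - a) / max(a, b)
    return s


def brute_knn(X: np.ndarray, k: int) -> list[list[int]]:
    """k nearest other points by exhaustive distances, ties by index."""
    n = len(X)
    out = []
    for i in range(n):
        d = [(float(((X[i] - X[j]) ** 2).sum()), j) for j in range(n) if j != i]
        d.sort()
        out.append([j for _, j in d[:k]])
    return out


def brute_pwc(A: np.ndarray, codes: np.ndarray) -> dict[int, float]:
    """Per-class weak-cell fraction by explicit degree splitting."""
    n = len(codes)
    per_class: dict[int, float] = {}
    for cls in dict.fromkeys(codes.tolist()):
        members = [i for i in range(n) if codes[i] == cls]
        weak = 0
        for i in members:
            k_in = sum(1 for j in range(n) if A[i, j] > 0 and codes[j] == cls)
            k_out = sum(1 for j in range(n) if A[i, j] > 0 and codes[j] != cls)
            if k_in < k_out:
                weak += 1
        per_class[cls] = weak / len(members)
    return per_class


def brute_foscttm(X1: np.ndarray, X2: np.ndarray) -> float:
    """FOSCTTM by explicit cosine distances and rank counting."""

    def cos_d(a, b):
        return 1 - float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))

    n = len(X1)
    fracs = []
    for i in range(n):
        d_true = cos_d(X1[i], X2[i])
        r_fwd = sum(1 for j in range(n) if cos_d(X1[i], X2[j]) <= d_true)
        r_rev = sum(1 for j in range(n) if cos_d(X1[j], X2[i]) <= d_true)
        fracs.append(((r_fwd - 1) + (r_rev - 1)) / (2 * (n - 1)))
    return float(np.mean(fracs))
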