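"""Graph-level evaluation: the Proportion of Weakly Connected cells (PWC).

Following the strong-community criterion of Radicchi et al., a cell is
*weakly connected* to its own class when it has strictly fewer graph
connections inside the subgraph of its class than toward the rest of the
graph.  PWC reports, per class, the fraction of such cells; 0 means every
class is a strong community on the graph.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .io_core import LabelVector, NeighborGraph

__all__ = ["PwcResult", "pwc"]

from dataclasses import dataclass


@dataclass
class PwcResult:
    per_class: dict[str, float]
    mean: float
    weak_cells: dict[str, list[str]]


def pwc(graph: NeighborGraph, labels: LabelVector, weighted: bool = False) -> PwcResult:
    """Proportion of weakly connected cells per class.

    For cell i in class V: k_in = edges (or, with ``weighted``, total edge
    weight) from i into V, k_out = the same toward the complement; i is
    weak iff k_in < k_out (strict, so degree-0 cells are never weak).
    The mean is the unweighted average over classes.
    """
    A = graph.adjacency
    if not weighted:
        A = sp.csr_matrix((np.ones_like(A.data), A.indices, A.indptr), shape=A.shape)
    codes = labels.codes()
    K = labels.K
    onehot = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), K),
    )
    k_by_class = np.asarray((A @ onehot).todense())  # (n, K) degree into each class
    k_in = k_by_class[np.arange(len(codes)), codes]
    k_out = k_by_class.sum(axis=1) - k_in
    weak = k_in < k_out
    per_class: dict[str, float] = {}
    weak_cells: dict[str, list[str]] = {}
    for c, cls in enumerate(labels.classes):
        mask = codes == c
        per_class[cls] = float(weak[mask].mean())
        weak_cells[cls] = [
            graph.cell_ids[i] for i in np.flatnonzero(mask & weak)
        ]
    return PwcResult(
        per_class=per_class,
        mean=float(np.mean(list(per_class.values()))),
        weak_cells=weak_cells,
    )
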