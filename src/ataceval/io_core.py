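"""Domain types and file I/O for the evaluation toolkit.

All metrics operate on a small set of in-memory containers defined here:
per-cell embedding coordinates, categorical label/cluster assignments,
sparse neighbor graphs, per-cell library sizes, and a serializable report
of metric values.  On-disk formats are plain text: delimited tables
(comma or tab, auto-detected) for embeddings/labels/library sizes,
MatrixMarket or 3-column edge lists for graphs, and JSON/TSV for reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("ataceval")

__all__ = [
    "FormatError",
    "ParameterError",
    "EmbeddingMatrix",
    "LabelVector",
    "Partition",
    "NeighborGraph",
    "LibrarySizeVector",
    "MetricReport",
    "read_embedding",
    "write_embedding",
    "read_labels",
    "read_partition",
    "write_labels",
    "read_libsize",
    "write_libsize",
    "read_graph",
    "write_graph",
    "align",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class ParameterError(ValueError):
    """Raised when a caller-supplied parameter is out of its valid range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_unique_ids(cell_ids: Sequence[str]) -> tuple[str, ...]:
    ids = tuple(str(c) for c in cell_ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for c in ids:
            if c in seen:
                raise FormatError(f"duplicate cell id {c!r}")
            seen.add(c)
    return ids


@dataclass
class EmbeddingMatrix:
    """Cells × latent-dimensions coordinate matrix with cell identifiers.

    Latent coordinates are unitless (output of a dimensional-reduction
    method).  Rows align with ``cell_ids``.
    """

    cell_ids: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique_ids(self.cell_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise FormatError("coords must be a 2-D matrix")
        n, d = self.coords.shape
        if n < 2:
            raise FormatError("embedding needs at least 2 cells")
        if d < 1:
            raise FormatError("embedding needs at least 1 dimension")
        if len(self.cell_ids) != n:
            raise FormatError("cell_ids length does not match coords rows")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("embedding contains non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class LabelVector:
    """Ground-truth class assignment per cell (e.g., annotated cell types)."""

    cell_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique_ids(self.cell_ids)
        self.labels = tuple(str(x) for x in self.labels)
        if len(self.labels) != len(self.cell_ids):
            raise FormatError("labels length does not match cell_ids")
        if len(self.labels) == 0:
            raise FormatError("no records")

    @property
    def K(self) -> int:
        """Number of distinct classes."""
        return len(set(self.labels))

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct classes in order of first appearance."""
        return tuple(dict.fromkeys(self.labels))

    def codes(self) -> np.ndarray:
        """Integer codes (first-appearance order)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.fromiter((lut[x] for x in self.labels), dtype=np.int64)


@dataclass
class Partition(LabelVector):
    """Predicted cluster assignment per cell (same shape as LabelVector)."""

    @property
    def J(self) -> int:
        """Number of distinct clusters."""
        return self.K

    @property
    def clusters(self) -> tuple[str, ...]:
        return self.classes


@dataclass
class NeighborGraph:
    """Sparse symmetric weighted graph over cells (kNN or SNN).

    Edge weights are unitless; the diagonal is zero and symmetry is
    enforced to a 1e-9 tolerance on construction.
    """

    cell_ids: tuple[str, ...]
    adjacency: sp.csr_matrix
    kind: str = "knn"

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique_ids(self.cell_ids)
        if self.kind not in ("knn", "snn"):
            raise ParameterError(f"unknown graph kind {self.kind!r}")
        A = sp.csr_matrix(self.adjacency, dtype=float)
        n = len(self.cell_ids)
        if A.shape != (n, n):
            raise FormatError("adjacency shape does not match cell_ids")
        if A.nnz and A.data.min() < 0:
            raise FormatError("negative edge weight")
        if A.nnz:
            asym = abs(A - A.T)
            if asym.nnz and asym.max() > 1e-9:
                raise FormatError("adjacency not symmetric within 1e-9")
        if np.any(A.diagonal() != 0):
            logger.warning("dropping nonzero diagonal entries from graph")
            A = sp.csr_matrix(A - sp.diags(A.diagonal()))
        A.eliminate_zeros()
        self.adjacency = A

    @property
    def n(self) -> int:
        return len(self.cell_ids)


@dataclass
class LibrarySizeVector:
    """Total unique fragments per cell (a non-negative integer count)."""

    cell_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique_ids(self.cell_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) != len(self.cell_ids):
            raise FormatError("counts length does not match cell_ids")
        if np.any(counts < 0):
            raise FormatError("library sizes must be non-negative")
        self.counts = counts.astype(np.int64)


_REPORT_LEVELS = ("embedding", "graph", "partition", "sweep", "bias", "integration")


@dataclass
class MetricReport:
    """Named metric values at one evaluation level, serializable to JSON/TSV.

    Undefined values are stored as NaN in memory and written as JSON null.
    """

    level: str
    values: dict[str, float | None] = field(default_factory=dict)
    per_group: dict[str, dict[str, float | None]] | None = None

    def __post_init__(self) -> None:
        if self.level not in _REPORT_LEVELS:
            raise ParameterError(f"unknown report level {self.level!r}")

    @staticmethod
    def _clean(v: float | None) -> float | None:
        if v is None:
            return None
        v = float(v)
        return None if math.isnan(v) else v

    def to_dict(self) -> dict:
        out: dict = {"level": self.level,
                     "values": {k: self._clean(v) for k, v in self.values.items()}}
        if self.per_group is not None:
            out["per_group"] = {
                g: {k: self._clean(v) for k, v in d.items()}
                for g, d in self.per_group.items()
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        rows = [("metric", "group", "value")]
        for k, v in self.values.items():
            c = self._clean(v)
            rows.append((k, "", "" if c is None else repr(c)))
        if self.per_group:
            for g, d in self.per_group.items():
                for k, v in d.items():
                    c = self._clean(v)
                    rows.append((k, g, "" if c is None else repr(c)))
        Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n")


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    # comma/tab auto-detection: both occur in single-cell exports
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _read_table(path: str | Path, delimiter: str | None) -> tuple[list[list[str]], str]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"no records in {path}")
    delim = _sniff_delimiter(lines[0], delimiter)
    return [ln.split(delim) for ln in lines], delim


def _is_float(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_embedding(path: str | Path, delimiter: str | None = None) -> EmbeddingMatrix:
    """Read a cells × dimensions table: first column cell id, rest numeric.

    A header row is auto-detected (non-numeric coordinate fields on the
    first line only).
    """
    rows, _ = _read_table(path, delimiter)
    if len(rows) > 1 and not all(_is_float(x) for x in rows[0][1:]):
        rows = rows[1:]  # header
    cell_ids = [r[0].strip() for r in rows]
    width = len(rows[0])
    coords = np.empty((len(rows), width - 1), dtype=float)
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(f"row {i + 1} has {len(r)} fields, expected {width}")
        for j, tok in enumerate(r[1:]):
            try:
                coords[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"non-numeric coordinate at row {i + 1}, column {j + 2}: {tok!r}"
                ) from None
    return EmbeddingMatrix(tuple(cell_ids), coords)


def write_embedding(emb: EmbeddingMatrix, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for cid, row in zip(emb.cell_ids, emb.coords):
            fh.write(cid + delimiter + delimiter.join(repr(float(v)) for v in row) + "\n")


def _read_two_col(path: str | Path, delimiter: str | None) -> tuple[list[str], list[str]]:
    rows, _ = _read_table(path, delimiter)
    if len(rows) > 1 and len(rows[0]) >= 2 and rows[0][0].strip().lower() in (
        "cell", "cell_id", "barcode", "id"
    ):
        rows = rows[1:]
    ids, vals = [], []
    for i, r in enumerate(rows):
        if len(r) < 2:
            raise FormatError(f"row {i + 1}: expected 2 columns")
        ids.append(r[0].strip())
        vals.append(r[1].strip())
    return ids, vals


def read_labels(path: str | Path, delimiter: str | None = None) -> LabelVector:
    """Read a two-column (cell id, label) table into a LabelVector."""
    ids, vals = _read_two_col(path, delimiter)
    return LabelVector(tuple(ids), tuple(vals))


def read_partition(path: str | Path, delimiter: str | None = None) -> Partition:
    """Read a two-column (cell id, cluster) table into a Partition."""
    ids, vals = _read_two_col(path, delimiter)
    return Partition(tuple(ids), tuple(vals))


def write_labels(labels: LabelVector, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for cid, lab in zip(labels.cell_ids, labels.labels):
            fh.write(f"{cid}{delimiter}{lab}\n")


def read_libsize(path: str | Path, delimiter: str | None = None) -> LibrarySizeVector:
    """Read a two-column (cell id, fragment count) table."""
    ids, vals = _read_two_col(path, delimiter)
    counts = np.empty(len(vals), dtype=np.int64)
    for i, v in enumerate(vals):
        try:
            counts[i] = int(float(v))
        except ValueError:
            raise FormatError(f"non-numeric library size at row {i + 1}: {v!r}") from None
    return LibrarySizeVector(tuple(ids), counts)


def write_libsize(ls: LibrarySizeVector, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for cid, c in zip(ls.cell_ids, ls.counts):
            fh.write(f"{cid}{delimiter}{int(c)}\n")


# ---------------------------------------------------------------------------
# Graph readers/writers
# ---------------------------------------------------------------------------


def _symmetrize_max(A: sp.spmatrix) -> sp.csr_matrix:
    # elementwise max: idempotent on symmetric inputs, completes
    # upper-triangle-only writers
    A = sp.csr_matrix(A)
    return A.maximum(A.T)


def read_graph(
    path: str | Path,
    format: str = "mtx",
    kind: str = "knn",
    cell_ids: Sequence[str] | None = None,
) -> NeighborGraph:
    """Read a neighbor graph from MatrixMarket or a 3-column edge list.

    Edge lists name cells directly (i-id, j-id, weight); MatrixMarket is
    positional, so ``cell_ids`` may be supplied (defaults to ``cell{i}``).
    The adjacency is symmetrized by elementwise max and the diagonal dropped.
    """
    if format == "mtx":
        A = sp.coo_matrix(scipy.io.mmread(str(path)))
        if A.shape[0] != A.shape[1]:
            raise FormatError("graph matrix must be square")
        if A.nnz and A.data.min() < 0:
            raise FormatError("negative edge weight")
        n = A.shape[0]
        ids = tuple(cell_ids) if cell_ids is not None else tuple(
            f"cell{i}" for i in range(n)
        )
        if len(ids) != n:
            raise FormatError("cell_ids length does not match matrix size")
        return NeighborGraph(ids, _symmetrize_max(A), kind=kind)
    if format == "edgelist":
        rows, _ = _read_table(path, None)
        if cell_ids is not None:
            ids = list(cell_ids)
            index = {c: i for i, c in enumerate(ids)}
        else:
            ids, index = [], {}
        ii, jj, ww = [], [], []
        for r, rec in enumerate(rows):
            if len(rec) < 3:
                raise FormatError(f"edge list row {r + 1}: expected 3 columns")
            a, b, w = rec[0].strip(), rec[1].strip(), float(rec[2])
            if w < 0:
                raise FormatError(f"negative edge weight at row {r + 1}")
            for c in (a, b):
                if c not in index:
                    if cell_ids is not None:
                        raise FormatError(f"unknown cell id {c!r} in edge list")
                    index[c] = len(ids)
                    ids.append(c)
            ii.append(index[a])
            jj.append(index[b])
            ww.append(w)
        n = len(ids)
        A = sp.coo_matrix((ww, (ii, jj)), shape=(n, n))
        return NeighborGraph(tuple(ids), _symmetrize_max(A), kind=kind)
    raise ParameterError(f"unknown graph format {format!r}")


def write_graph(graph: NeighborGraph, path: str | Path, format: str = "mtx") -> None:
    if format == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(graph.adjacency), symmetry="general")
    elif format == "edgelist":
        A = sp.triu(graph.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            for i, j, w in zip(A.row, A.col, A.data):
                fh.write(f"{graph.cell_ids[i]}\t{graph.cell_ids[j]}\t{float(w)!r}\n")
    else:
        raise ParameterError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _take(obj, idx: np.ndarray):
    ids = tuple(obj.cell_ids[i] for i in idx)
    if isinstance(obj, EmbeddingMatrix):
        return EmbeddingMatrix(ids, obj.coords[idx])
    if isinstance(obj, Partition):
        return Partition(ids, tuple(obj.labels[i] for i in idx))
    if isinstance(obj, LabelVector):
        return LabelVector(ids, tuple(obj.labels[i] for i in idx))
    if isinstance(obj, NeighborGraph):
        return NeighborGraph(ids, obj.adjacency[np.ix_(idx, idx)], kind=obj.kind)
    if isinstance(obj, LibrarySizeVector):
        return LibrarySizeVector(ids, obj.counts[idx])
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


def align(*objects) -> tuple:
    """Restrict and reorder objects to their common cell-id set.

    The common cells keep the order they have in the first object.  Returns
    the aligned objects followed by the number of cells dropped (summed over
    objects).  Idempotent: aligning aligned objects drops nothing.
    """
    if len(objects) < 2:
        raise ParameterError("align needs at least 2 objects")
    common = set(objects[0].cell_ids)
    for obj in objects[1:]:
        common &= set(obj.cell_ids)
    if len(common) < 2:
        raise FormatError("fewer than 2 cells shared between inputs")
    order = [c for c in objects[0].cell_ids if c in common]
    dropped = sum(len(obj.cell_ids) - len(order) for obj in objects)
    if dropped:
        logger.info("align: dropped %d cell entries outside the common set", dropped)
    out = []
    for obj in objects:
        pos = {c: i for i, c in enumerate(obj.cell_ids)}
        idx = np.fromiter((pos[c] for c in order), dtype=np.int64)
        out.append(_take(obj, idx))
    return (*out, dropped)
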