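"""Synthetic data with the statistical structure the metrics assume.

Embeddings are Gaussian mixtures: class means placed at a controlled
pairwise distance (``separation``, in units of the within-class standard
deviation), unit isotropic within-class noise, optional nested subclass
structure, log-normal library sizes with an optional loading of
sqrt(library size) onto the first latent dimension (emulating the depth
leakage of LSI-style reductions), and a second modality obtained by
additive Gaussian noise.  Partition perturbations (merge, split, random
relabel) produce predictions with known kinds of error.  All randomness
flows through one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .integration_metrics import PairedEmbeddings
from .io_core import (
    EmbeddingMatrix,
    LabelVector,
    LibrarySizeVector,
    ParameterError,
    Partition,
)

__all__ = [
    "HierarchySpec",
    "SimConfig",
    "simulate_embedding",
    "perturb_partition",
    "simulate_paired",
]


@dataclass(frozen=True)
class HierarchySpec:
    """Nested structure: every class splits into subclasses at a smaller
    separation (units of within-class s.d.)."""

    n_subclasses: int = 2
    sub_separation: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``separation`` is the pairwise distance between class means in units
    of the (unit) within-class standard deviation: 0 removes all spatial
    signal, values ≫ √(2·n_dims) give fully separated classes.  Library
    sizes are log-normal; the defaults (mu=8.5, sigma=0.5) give a median
    of ≈5,000 unique fragments per cell, a typical scATAC-seq depth.
    ``bias_loading`` adds that coefficient times sqrt(library size) to
    dimension 1, mimicking depth leakage into the leading component.
    """

    n_cells: int = 2000
    class_proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    n_dims: int = 15
    separation: float = 8.0
    hierarchy: HierarchySpec | None = None
    libsize_mu: float = 8.5
    libsize_sigma: float = 0.5
    bias_loading: float = 0.0
    noise_sigma_modality2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ParameterError("class proportions must sum to 1")
        if min(self.class_proportions) <= 0:
            raise ParameterError("class proportions must be positive")
        for name in ("separation", "libsize_sigma", "noise_sigma_modality2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _class_sizes(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder rounding of proportions to integer class sizes."""
    raw = np.asarray(proportions) * n
    sizes = np.floor(raw).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(raw - np.floor(raw))[::-1]
    sizes[order[:rem]] += 1
    if np.any(sizes == 0):
        raise ParameterError("a class received 0 cells: increase n_cells")
    return sizes


def _spread_means(
    n_points: int, n_dims: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Points at pairwise distance ≈ separation (exact when they fit in
    orthogonal directions)."""
    if separation == 0:
        return np.zeros((n_points, n_dims))
    scale = separation / math.sqrt(2.0)
    G = rng.standard_normal((n_dims, n_points))
    if n_points <= n_dims:
        Q, _ = np.linalg.qr(G)
        return scale * Q[:, :n_points].T
    U = G / np.linalg.norm(G, axis=0, keepdims=True)
    return scale * U.T


def simulate_embedding(
    config: SimConfig = SimConfig(),
) -> tuple[EmbeddingMatrix, LabelVector, LibrarySizeVector]:
    """Gaussian-mixture embedding with labels and library sizes.

    With a ``hierarchy``, labels carry the subclass identity as
    ``"C{i}.{j}"``; the parent class is the part before the dot.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _class_sizes(config.n_cells, config.class_proportions)
    K = len(sizes)
    means = _spread_means(K, config.n_dims, config.separation, rng)
    cell_ids = tuple(f"cell{i}" for i in range(config.n_cells))
    coords = np.empty((config.n_cells, config.n_dims))
    labels: list[str] = []
    start = 0
    for k, size in enumerate(sizes):
        block = slice(start, start + size)
        coords[block] = means[k] + rng.standard_normal((size, config.n_dims))
        if config.hierarchy is None:
            labels += [f"C{k}"] * size
        else:
            h = config.hierarchy
            offsets = _spread_means(h.n_subclasses, config.n_dims, h.sub_separation, rng)
            sub = rng.integers(0, h.n_subclasses, size=size)
            coords[block] += offsets[sub]
            labels += [f"C{k}.{s}" for s in sub]
        start += size
    counts = np.maximum(
        1,
        np.round(
            rng.lognormal(config.libsize_mu, config.libsize_sigma, config.n_cells)
        ).astype(np.int64),
    )
    if config.bias_loading > 0:
        coords[:, 0] += config.bias_loading * np.sqrt(counts)
    return (
        EmbeddingMatrix(cell_ids, coords),
        LabelVector(cell_ids, tuple(labels)),
        LibrarySizeVector(cell_ids, counts),
    )


def perturb_partition(
    labels: LabelVector,
    action: str,
    seed: int = 0,
    merge_classes: tuple[str, ...] | None = None,
    split_class: str | None = None,
    split_parts: int = 2,
    relabel_fraction: float = 0.0,
) -> Partition:
    """Derive a predicted partition from the labels by a controlled error.

    ``merge`` joins the named classes into one cluster (completeness kept,
    homogeneity broken); ``split`` divides one class uniformly at random
    into parts (the mirror case); ``relabel`` reassigns ⌈ε·n⌉ random
    cells to uniform random clusters.
    """
    rng = np.random.default_rng(seed)
    out = list(labels.labels)
    if action == "merge":
        if merge_classes is None or len(merge_classes) < 2:
            raise ParameterError("merge needs >= 2 class names")
        missing = set(merge_classes) - set(labels.classes)
        if missing:
            raise ParameterError(f"unknown classes: {sorted(missing)}")
        merged_name = "+".join(merge_classes)
        out = [merged_name if x in merge_classes else x for x in out]
    elif action == "split":
        if split_class is None or split_class not in labels.classes:
            raise ParameterError("split needs an existing class name")
        members = [i for i, x in enumerate(out) if x == split_class]
        if split_parts > len(members):
            raise ParameterError("split parts exceed class size")
        assignment = rng.integers(0, split_parts, size=len(members))
        # guarantee every shard is non-empty
        assignment[rng.permutation(len(members))[:split_parts]] = np.arange(split_parts)
        for i, part in zip(members, assignment):
            out[i] = f"{split_class}/{part}"
    elif action == "relabel":
        if not 0 <= relabel_fraction <= 1:
            raise ParameterError("relabel fraction must be in [0, 1]")
        n = len(out)
        n_move = math.ceil(relabel_fraction * n)
        targets = list(labels.classes)
        idx = rng.choice(n, size=n_move, replace=False)
        for i in idx:
            out[i] = targets[rng.integers(0, len(targets))]
    else:
        raise ParameterError(f"unknown action {action!r}")
    return Partition(labels.cell_ids, tuple(out))


def simulate_paired(config: SimConfig = SimConfig()) -> PairedEmbeddings:
    """Two modalities of the same cells: X2 = X1 + isotropic Gaussian noise."""
    emb, _, _ = simulate_embedding(config)
    rng = np.random.default_rng(config.seed + 1)
    noise = config.noise_sigma_modality2 * rng.standard_normal(emb.coords.shape)
    return PairedEmbeddings(emb.coords, emb.coords + noise, cell_ids=emb.cell_ids)
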