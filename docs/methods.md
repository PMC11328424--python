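# Methods

`ataceval` scores the quality of single-cell chromatin (scATAC-seq)
processing pipelines at three stages of the standard clustering workflow:
the low-dimensional cell embedding, the shared-nearest-neighbor (SNN)
graph built from it, and the final graph-based partition.  Ground truth is
a per-cell class annotation (cell types).  This note records the models,
conventions, and numerical choices behind each statistic, plus the design
of the synthetic generator the test suite runs on.

## Embedding-level metrics

**Silhouette (ASW, FNS).**  For cell *i* with mean intra-class distance
*a(i)* (self excluded) and *b(i)* the smallest mean distance to another
class, *s(i) = (b − a)/max(a, b)* using Euclidean distance.  Cells in
singleton classes get *s = 0* (the standard convention; per-cell values
are delegated to scikit-learn, which applies the same rule).  ASW and the
fraction of negative silhouettes (FNS) are first averaged per class and
then across classes with equal weight, so abundant classes do not drown
out rare ones.  Raw silhouettes are not comparable across embeddings with
different global scales; FNS only depends on the *sign* of *s(i)* and is
therefore invariant to positive rescaling, which is why it is reported
alongside ASW.

**cLISI.**  The cluster-level Local Inverse Simpson Index of cell *i* is
`1 / Σ_c p_i(c)²` where *p_i(c)* sums Gaussian-kernel weights of *i*'s
`k_neighbors` nearest neighbors belonging to class *c*.  The kernel
bandwidth is calibrated per cell by bisection on log-bandwidth so that the
Shannon entropy of the normalized weights equals `log(perplexity)`
(at most 100 iterations, entropy tolerance 1e-5; degenerate neighborhoods
that cannot reach the target entropy fall back to uniform weights with a
logged warning).  Defaults are perplexity 30 and `k_neighbors = 90 =
3 × perplexity`, the convention of the reference LISI implementation.
The score lies in [1, K]: 1 for pure neighborhoods, K for complete
mixing.  Note that the upper bound K is a supremum: with a perplexity-30
kernel, the weight distribution has roughly 15–20 effective neighbors, so
even completely random balanced labels yield a mean around 3.3 for K = 4
(sampling variance of the neighborhood class proportions inflates
Σ p(c)²).  K is approached only as perplexity → ∞.  Scale invariance
holds to the bisection tolerance, not to machine precision.

## Graph-level metric

**PWC.**  Following the strong-community criterion (a community where
every member has more internal than external connections), a cell is
*weakly connected* when its edge count (or, optionally, total SNN edge
weight) into its own class is strictly smaller than toward the rest of
the graph.  `k_in = k_out` is not weak, and degree-0 cells are never weak
(0 < 0 is false).  The per-class fractions are averaged with equal class
weight.  The unweighted (edge-count) form is the default; the weighted
form is provided for sensitivity analyses on SNN weights.

## Graph construction

kNN search is exact (chunked pairwise distances, no approximate index),
with distance ties broken by ascending cell index via a stable sort, so
results are reproducible bit-for-bit.  The SNN weight between cells *i*
and *j* is the Jaccard overlap `|N(i) ∩ N(j)| / |N(i) ∪ N(j)|` of their
k-nearest-neighbor sets, **each set including the cell itself** (so
|N(i)| = k — the Seurat convention); weights at or below the prune
threshold are dropped.  Defaults k = 20, prune = 1/15 follow the same
delegated implementation.  `build_knn`'s `k`, by contrast, counts
neighbors *excluding* self, which is the usual meaning for a kNN graph;
the two conventions are stated explicitly because the overlap weights
depend on them.

## Partition-level metrics

With contingency table `n_ij` between classes U (sizes `n_i+`) and
clusters Z (sizes `n_+j`), and pair counts `N = C(n,2)`,
`P = Σ_i C(n_i+, 2)`, `Q = Σ_j C(n_+j, 2)`, `T = Σ_ij C(n_ij, 2)`:

* **AW, AV** — the two Wallace indices `T/P` and `T/Q`, adjusted for
  chance as `(S − E[S])/(1 − E[S])` with hypergeometric expectations
  `E[T/P] = Q/N`, `E[T/Q] = P/N`:

      AW = (N·T − P·Q) / (P·(N − Q)),   AV = (N·T − P·Q) / (Q·(N − P))

  AW measures completeness of classes, AV homogeneity of clusters.  The
  per-class and per-cluster decompositions AW_i, AV_j replace T, P (resp.
  T, Q) by their single-row (column) terms.  Singleton classes (P_i = 0)
  have undefined AW_i; these are reported as NaN in memory and null in
  JSON, never imputed.

* **ARI** is the harmonic mean of AW and AV, computed through the
  algebraically simplified closed form `2(N·T − P·Q)/(P(N−Q) + Q(N−P))`
  (identical to the classic Hubert–Arabie index), which stays defined in
  one-sided degenerate cases such as a single predicted cluster.  A
  second, independent route expresses ARI as a weighted average of the
  decompositions with weights `P_i(N−Q)` and `Q_j(N−P)`; weights of this
  form (rather than bare pair counts `P_i`, `Q_j`) are required for the
  weighted average to coincide with the harmonic mean when P ≠ Q, and the
  two routes are asserted to agree to 1e-12.

* **ARI2** is the harmonic mean `2·AW′·AV′/(AW′ + AV′)` of the
  *unweighted* means AW′ = mean_i AW_i and AV′ = mean_j AV_j, so a
  misassigned rare class costs as much as a misassigned abundant one.
  The harmonic-mean numerator `2·AW′·AV′` is forced by the
  identical-partition limit (ARI2 must equal 1 when every component is
  1).  Undefined singleton components are excluded from the means with a
  warning.  Caveat: a harmonic mean of opposite-signed quantities is
  unstable near AW′ + AV′ = 0 and can leave [−1, 1]; ARI2 is meaningful
  for broadly sensible clusterings, not adversarial ones.

* **MI, VI** use natural logarithms and the `0·log 0 := 0` convention,
  so the identities `MI = H(Z) − H(Z|U)` and `VI = H(U|Z) + H(Z|U)` hold
  exactly (asserted to 1e-12 against the direct definitions).  Both are
  unnormalized; they are comparable only within one dataset.

* **Evenness** `E = exp(H(U))/K ∈ [1/K, 1]` summarizes class balance of
  the annotation itself.

## Sweeps, AUC, stability

Partitions are scored over a grid of clustering resolutions × random
seeds (defaults: resolutions 0.1–2.0 in steps of 0.1; seeds 0, 2, 5, 42,
123).  Clustering is a pluggable callback — typically a Leiden run on the
SNN graph — and is deliberately not part of this library, so its
stochasticity never enters the deterministic test surface.  For each
metric, values are averaged at each observed cluster number and the
trapezoidal area of this mean curve over the observed cluster-number
range is divided by (upper bound × range width).  Upper bound 1 for
ARI/ARI2/AW/AV; for the unbounded MI and VI the sweep's own empirical
maximum is used, and VI (lower = better) is reported as 1 − normalized
AUC.  The averaged-curve (rather than per-point scatter) integrand
matches the mean-line summary used when such curves are plotted.

To compare AUC matrices (methods × metrics) across datasets on one color
scale, each column is centered on its median and the whole matrix is
divided by the median of all absolute deviations; a constant matrix maps
to zeros by convention.

Stability: per resolution, each pair of seeds is compared by the ARI
between their two partitions and the deviation 1 − ARI is averaged over
pairs, then over resolutions.  0 = seeds always agree up to relabeling;
≈1 = chance-level agreement.

## Library-size bias

Depth leakage per latent dimension is the absolute Pearson correlation
between sqrt(library size) and the dimension's coordinates, computed
*within* each class (between-class depth differences can be biology;
within-class ones are technical) and averaged over classes; the summary
averages the first five dimensions.  Classes with fewer than 3 cells or
zero variance are skipped with a warning.  The component filter mirrors
common LSI practice: a dimension is dropped when its correlation with
**raw** total counts across *all* cells exceeds the threshold (default
0.75) in absolute value — deliberately a different procedure (no sqrt, no
stratification) from the leakage score, matching how the two are used in
practice.

Geary's C on a kNN graph (k = 20 by default),

    C = (N−1)·Σ_ij w_ij (x_i − x_j)² / (2·S₀·Σ_i (x_i − x̄)²),

with S₀ the sum of all weights, both double sums running over the full
symmetric adjacency.  The CLI applies it to log1p-transformed fragment
counts (natural log; log1p tolerates zero-count cells).  C ≈ 1 for
spatially unstructured signals; values below 1 indicate the signal varies
smoothly over the embedding, i.e. depth structure in the latent space.

## FOSCTTM

For row-aligned embeddings X₁, X₂ of the same cells, `d_ij` is the cosine
distance (1 − cosine similarity) between row i of X₁ and row j of X₂;
`R_i` counts cells j with `d_ij ≤ d_ii` — ties count **against** the
match, the conservative convention — and `frac_i = (R_i − 1)/(n − 1)`.
Both directions are averaged per cell.  0 means every cell's true match
is nearest; independent embeddings average 0.5.

## Synthetic generator

The generator produces the regimes the metrics are designed to separate,
with no external data:

* **Geometry** — K class means placed at exact pairwise distance
  `separation` (orthonormal random directions scaled by separation/√2;
  random unit directions when K exceeds the dimension), plus unit
  isotropic Gaussian within-class noise.  `separation` is therefore in
  units of the per-dimension within-class standard deviation;
  `separation = 0` removes all spatial signal and values well above
  √(2·n_dims) give fully separated classes.  A consequence worth knowing:
  even at separation 50 in 15 dimensions the expected ASW is
  ≈ 1 − √(2·15)/50 ≈ 0.89, because the within-class *radius* grows with
  √dims while silhouettes compare full distances — near-1 silhouettes
  require separations large relative to √(2·n_dims), not to 1.
* **Defaults** — n = 2000 cells, proportions (0.4, 0.3, 0.2, 0.1) so a
  rare class exists, 15 dimensions (the usual post-elbow choice for this
  data type), separation 8 (partially overlapping neighbors: a regime
  where metrics disagree informatively).
* **Library sizes** — log-normal with mu = 8.5, sigma = 0.5 (median
  ≈ 4.9k unique fragments, 95% range ≈ 1.8k–13k), a typical droplet
  scATAC-seq depth profile.  `bias_loading` adds that coefficient times
  sqrt(library size) to dimension 1, reproducing the depth leakage of
  LSI-style embeddings.
* **Hierarchy** — optionally each class splits into subclasses offset at
  a smaller separation; labels are `"C{i}.{j}"` with the parent
  recoverable as the prefix.
* **Perturbations** — `merge` (under-clustering: completeness kept,
  homogeneity broken), `split` (over-clustering: the mirror), `relabel`
  (uniform noise on a fraction of cells).
* **Paired modalities** — X₂ = X₁ + isotropic Gaussian noise.

All randomness flows through one `numpy` Generator seeded per call;
outputs are bit-identical for identical configurations.

What the generator does *not* emulate: anisotropic or class-dependent
covariance, non-Gaussian manifold structure, batch effects, doublets, and
the sparsity/binarity of the underlying count data (it produces
embeddings directly).  Passing tests therefore certify the metrics'
mathematical behavior and implementation, not any claim about a specific
real dataset or feature-engineering method.

## Numerical conventions and degenerate inputs

* Undefined metric components are NaN in memory, null in JSON — never a
  silent 0.
* Graph symmetrization on read uses the elementwise max (idempotent,
  completes upper-triangle-only files); nonzero diagonals are dropped
  with a warning; asymmetry beyond 1e-9 is an error.
* Cell-id matching is exact, case-sensitive string equality; `align`
  restricts inputs to the common id set in the first object's order and
  is idempotent.
* Distance ties everywhere resolve by ascending cell index.
* Trivial partitions (one cluster) leave AW undefined but ARI and AV
  well-defined (both 0 for a non-trivial U).

## Problem sizes

The test suite and the acceptance script run entirely on generated data
at n ≤ 2000 cells, where every statistic is exact or tightly concentrated
(the oracle comparisons use n ≤ 200 with exhaustive enumeration).  These
sizes were chosen so the full suite completes in seconds while every
asymptotic claim (chance correction, mixing limits, null expectations)
is already within its stated tolerance.
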