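import numpy as np
import pytest
import scipy.sparse as sp

from ataceval import (
    EmbeddingMatrix,
    LabelVector,
    LibrarySizeVector,
    NeighborGraph,
    ParameterError,
    component_filter,
    gearys_c,
    library_size_correlation,
)


def triple(coords, labels, counts):
    ids = tuple(f"c{i}" for i in range(len(labels)))
    return (
        EmbeddingMatrix(ids, np.asarray(coords, dtype=float)),
        LabelVector(ids, tuple(map(str, labels))),
        LibrarySizeVector(ids, np.asarray(counts, dtype=np.int64)),
    )


class TestLibrarySizeCorrelation:
    def test_perfect_leakage_scores_one(self, rng):
        counts = rng.integers(100, 10000, 200)
        coords = np.column_stack([np.sqrt(counts), rng.standard_normal(200)])
        emb, lab, ls = triple(coords, rng.integers(0, 2, 200), counts)
        res = library_size_correlation(emb, lab, ls)
        assert res.per_dimension[1] == pytest.approx(1.0)

    def test_independent_dimension_small_r(self, rng):
        n = 500
        counts = rng.integers(1000, 5000, n)
        coords = rng.standard_normal((n, 1))
        emb, lab, ls = triple(coords, [0] * n, counts)
        res = library_size_correlation(emb, lab, ls)
        # |r| of independent samples concentrates near sqrt(2/(pi n))
        assert res.per_dimension[1] < 4 * np.sqrt(2 / (np.pi * n))

    def test_opposite_sign_correlations_average_absolutely(self, rng):
        # two classes with within-class correlation +-rho: the absolute
        # values average, signs do not cancel
        n = 4000
        counts = rng.integers(2500, 10000, n)
        root = np.sqrt(counts)
        z = (root - root.mean()) / root.std()
        noise = rng.standard_normal(n)
        rho = 0.8
        y = rho * z + np.sqrt(1 - rho**2) * noise
        y[n // 2:] = -y[n // 2:]
        emb, lab, ls = triple(y[:, None], [0] * (n // 2) + [1] * (n // 2), counts)
        res = library_size_correlation(emb, lab, ls)
        assert res.per_dimension[1] == pytest.approx(rho, abs=0.05)

    def test_small_and_constant_classes_skipped(self, rng):
        coords = rng.standard_normal((10, 1))
        coords[5:] = 3.14  # zero variance in class 1
        counts = rng.integers(100, 200, 10)
        emb, lab, ls = triple(coords, [0, 0, 0, 0, 0, 1, 1, 1, 1, 1], counts)
        res = library_size_correlation(emb, lab, ls)
        assert np.isfinite(res.per_dimension[1])  # class 0 still contributes

    def test_invariances(self, rng):
        n = 300
        counts = rng.integers(500, 5000, n)
        coords = rng.standard_normal((n, 3))
        labels = rng.integers(0, 3, n)
        emb, lab, ls = triple(coords, labels, counts)
        base = library_size_correlation(emb, lab, ls)
        emb2, _, _ = triple(coords * np.array([5.0, -2.0, 0.1]) + 7.0, labels, counts)
        rescaled = library_size_correlation(emb2, lab, ls)
        for l in base.per_dimension:
            assert rescaled.per_dimension[l] == pytest.approx(base.per_dimension[l])
        _, _, ls4 = triple(coords, labels, counts * 4)
        scaled_ls = library_size_correlation(emb, lab, ls4)
        for l in base.per_dimension:
            assert scaled_ls.per_dimension[l] == pytest.approx(base.per_dimension[l])


class TestComponentFilter:
    def test_depth_component_removed(self, rng):
        counts = rng.integers(100, 10000, 100)
        coords = np.column_stack([counts.astype(float), rng.standard_normal(100)])
        emb, _, ls = triple(coords, [0] * 100, counts)
        kept, removed = component_filter(emb, ls, threshold=0.75)
        assert removed == [1] and kept == [2]

    def test_orthogonal_components_all_kept(self, rng):
        counts = rng.integers(100, 10000, 500)
        coords = rng.standard_normal((500, 5))
        emb, _, ls = triple(coords, [0] * 500, counts)
        kept, removed = component_filter(emb, ls)
        assert removed == [] and kept == [1, 2, 3, 4, 5]

    def test_threshold_one_keeps_non_collinear(self, rng):
        counts = rng.integers(100, 10000, 100)
        coords = np.column_stack([counts + rng.standard_normal(100), counts * 0.0 + rng.standard_normal(100)])
        emb, _, ls = triple(coords, [0] * 100, counts)
        kept, removed = component_filter(emb, ls, threshold=1.0)
        assert removed == []

    def test_all_removed_errors(self, rng):
        counts = rng.integers(100, 10000, 100)
        coords = counts.astype(float)[:, None]
        emb, _, ls = triple(coords, [0] * 100, counts)
        with pytest.raises(ParameterError, match="no informative"):
            component_filter(emb, ls)


def graph_from_dense(A):
    A = np.asarray(A, dtype=float)
    return NeighborGraph(tuple(f"c{i}" for i in range(len(A))), sp.csr_matrix(A))


class TestGearysC:
    def test_path_graph_hand_value(self):
        # path 0–1–2, x=(0,1,2): numerator (N−1)·ΣΣ w(xi−xj)² = 2·4,
        # denominator 2·S0·Σ(xi−x̄)² = 2·4·2
        g = graph_from_dense([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert gearys_c(g, np.array([0.0, 1.0, 2.0])) == pytest.approx(0.5)

    def test_random_signal_null_near_one(self, rng):
        import networkx as nx

        G = nx.random_regular_graph(6, 400, seed=3)
        A = nx.to_numpy_array(G)
        vals = [gearys_c(graph_from_dense(A), rng.standard_normal(400)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_component_constant_signal_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1
        A[2, 3] = A[3, 2] = 1
        x = np.array([5.0, 5.0, -1.0, -1.0])
        assert gearys_c(graph_from_dense(A), x) == 0.0

    def test_affine_and_weight_scale_invariance(self, rng):
        A = (rng.random((30, 30)) < 0.2).astype(float)
        A = np.triu(A, 1)
        A += A.T
        x = rng.standard_normal(30)
        base = gearys_c(graph_from_dense(A), x)
        assert gearys_c(graph_from_dense(A), 3.0 * x - 7.0) == pytest.approx(base)
        assert gearys_c(graph_from_dense(A * 0.25), x) == pytest.approx(base)
        assert base >= 0

    def test_constant_signal_errors(self):
        g = graph_from_dense([[0, 1], [1, 0]])
        with pytest.raises(ParameterError, match="zero variance"):
            gearys_c(g, np.array([2.0, 2.0]))
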