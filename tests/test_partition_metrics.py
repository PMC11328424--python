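import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from ataceval import (
    LabelVector,
    ParameterError,
    Partition,
    ari,
    ari2,
    contingency,
    evenness,
    mi_vi,
    score_partition,
    wallace_adjusted,
)
from oracles import brute_pair_stats


def pair(u, z):
    ids = tuple(f"c{i}" for i in range(len(u)))
    return (
        LabelVector(ids, tuple(map(str, u))),
        Partition(ids, tuple(map(str, z))),
    )


def random_pair(rng, n, ku, kz):
    return pair(rng.integers(0, ku, n), rng.integers(0, kz, n))


class TestContingency:
    def test_diagonal_table(self):
        c = contingency(*pair("AABB", "1122"))
        np.testing.assert_array_equal(c.n_ij, [[2, 0], [0, 2]])
        assert c.N == 6 and c.P == 2 and c.Q == 2

    def test_uniform_table_no_joint_pairs(self):
        c = contingency(*pair("AABB", "1212"))
        assert c.n_ij.tolist() == [[1, 1], [1, 1]]
        assert c.T == 0

    def test_single_cluster_has_Q_equal_N(self):
        c = contingency(*pair("AABB", "1111"))
        assert c.Q == c.N

    def test_too_few_cells(self):
        with pytest.raises(ParameterError):
            contingency(*pair("A", "1"))


class TestWallace:
    def test_identical_partitions_are_one(self):
        c = contingency(*pair("AABBB", "xxyyy"))
        aw, av, aw_i, av_j = wallace_adjusted(c)
        assert aw == av == 1.0
        np.testing.assert_allclose(aw_i, 1.0)
        np.testing.assert_allclose(av_j, 1.0)

    def test_crossed_partitions_negative(self):
        c = contingency(*pair("AABB", "1212"))
        aw, av, *_ = wallace_adjusted(c)
        assert aw == av == pytest.approx(-0.5)

    def test_chance_level_near_zero(self, rng):
        vals = []
        for _ in range(300):
            c = contingency(*random_pair(rng, 100, 4, 4))
            vals.append(wallace_adjusted(c)[0])
        assert abs(np.mean(vals)) < 0.02

    def test_trivial_clustering_flagged_undefined(self):
        c = contingency(*pair("AABB", "1111"))
        aw, av, *_ = wallace_adjusted(c)
        assert np.isnan(aw)  # denominator P(N−Q) = 0
        assert av == 0.0

    def test_symmetry_swaps_aw_and_av(self, rng):
        u, z = random_pair(rng, 60, 3, 5)
        c_fwd = contingency(u, z)
        c_rev = contingency(Partition(z.cell_ids, z.labels), LabelVector(u.cell_ids, u.labels))
        f = wallace_adjusted(c_fwd)
        r = wallace_adjusted(c_rev)
        assert f[0] == pytest.approx(r[1]) and f[1] == pytest.approx(r[0])
        np.testing.assert_allclose(f[2], r[3])
        np.testing.assert_allclose(f[3], r[2])


class TestAri:
    def test_identical_is_one(self):
        c = contingency(*pair("AABB", "1122"))
        assert ari(c) == (1.0, 1.0)

    def test_crossed_is_minus_half(self):
        c = contingency(*pair("AABB", "1212"))
        h, w = ari(c)
        assert h == pytest.approx(-0.5) and w == pytest.approx(-0.5)

    def test_unbalanced_example_matches_pair_enumeration(self):
        u, z = pair("AAAB", "1122")
        expected = brute_pair_stats(np.array(list("AAAB")), np.array(list("1122")))
        h, w = ari(contingency(u, z))
        assert h == pytest.approx(expected["ARI"], abs=1e-12)
        assert h == pytest.approx(adjusted_rand_score([0, 0, 0, 1], [0, 0, 1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_routes_agree_and_match_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        u, z = random_pair(rng, 80, rng.integers(2, 6), rng.integers(2, 6))
        c = contingency(u, z)
        h, w = ari(c)
        assert h == pytest.approx(w, abs=1e-12)
        sk = adjusted_rand_score(u.codes(), z.codes())
        assert h == pytest.approx(sk, abs=1e-10)


class TestAri2:
    def test_identical_is_one(self):
        c = contingency(*pair("AABBCC", "112233"))
        assert ari2(c) == pytest.approx(1.0)

    def test_crossed_is_minus_half(self):
        c = contingency(*pair("AABB", "1212"))
        assert ari2(c) == pytest.approx(-0.5)

    def test_rare_class_errors_weighted_up(self):
        # perfect recovery of a 90-cell class, 10-cell class split across
        # two shards: the unweighted decomposition means punish the
        # rare-class error far more than the pair-weighted ARI does
        u = ["big"] * 90 + ["rare"] * 10
        z = ["b"] * 90 + ["r1"] * 5 + ["r2"] * 5
        c = contingency(*pair(u, z))
        expected = brute_pair_stats(np.array(u), np.array(z))
        assert ari2(c) == pytest.approx(expected["ARI2"], abs=1e-10)
        assert ari2(c) < ari(c)[0]

    def test_singleton_components_excluded(self):
        u, z = pair("AAAB", "1112")
        c = contingency(u, z)
        # class B and cluster 2 are singletons: excluded, rest identical
        assert ari2(c) == pytest.approx(1.0)


class TestMiVi:
    def test_identical_balanced_two_class(self):
        res = mi_vi(contingency(*pair("AABB", "1122")))
        assert res["MI"] == pytest.approx(np.log(2), abs=1e-12)
        assert res["VI"] == pytest.approx(0.0, abs=1e-12)

    def test_product_table_zero_mi(self):
        res = mi_vi(contingency(*pair("AABB", "1212")))
        assert res["MI"] == pytest.approx(0.0, abs=1e-12)
        assert res["VI"] == pytest.approx(res["H_U"] + res["H_Z"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_entropy_route_identities(self, seed):
        rng = np.random.default_rng(seed)
        u, z = random_pair(rng, 70, 3, 4)
        res = mi_vi(contingency(u, z))
        assert res["MI"] == pytest.approx(res["H_Z"] - res["H_Z_given_U"], abs=1e-12)
        assert res["VI"] == pytest.approx(
            res["H_U"] + res["H_Z"] - 2 * res["MI"], abs=1e-12
        )
        sk = mutual_info_score(u.codes(), z.codes())
        assert res["MI"] == pytest.approx(sk, abs=1e-10)
        assert res["MI"] <= min(res["H_U"], res["H_Z"]) + 1e-12
        assert res["VI"] >= 0

    def test_vi_symmetric_and_zero_on_self(self, rng):
        u, z = random_pair(rng, 50, 3, 3)
        fwd = mi_vi(contingency(u, z))["VI"]
        rev = mi_vi(
            contingency(Partition(z.cell_ids, z.labels), LabelVector(u.cell_ids, u.labels))
        )["VI"]
        assert fwd == pytest.approx(rev, abs=1e-12)
        u2 = Partition(u.cell_ids, u.labels)
        assert mi_vi(contingency(u, u2))["VI"] == pytest.approx(0.0, abs=1e-12)


class TestEvenness:
    def test_balanced_is_one(self):
        lab = LabelVector(tuple(map(str, range(4))), ("A", "A", "B", "B"))
        assert evenness(lab) == pytest.approx(1.0)

    def test_three_quarters_split(self):
        lab = LabelVector(tuple(map(str, range(4))), ("A", "A", "A", "B"))
        h = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert evenness(lab) == pytest.approx(np.exp(h) / 2)
        assert evenness(lab) == pytest.approx(0.8774, abs=1e-4)

    def test_single_class_is_one(self):
        lab = LabelVector(("a", "b"), ("x", "x"))
        assert evenness(lab) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, rng.integers(2, 8), 50)
        lab = LabelVector(tuple(map(str, range(50))), tuple(map(str, vals)))
        e = evenness(lab)
        assert 1 / lab.K - 1e-12 <= e <= 1 + 1e-12


class TestScorePartition:
    def test_bundles_consistent_values(self, rng):
        u, z = random_pair(rng, 60, 3, 4)
        s = score_partition(u, z)
        c = contingency(u, z)
        assert s.ARI == pytest.approx(ari(c)[0])
        assert s.ARI2 == pytest.approx(ari2(c))
        assert set(s.AW_i) == set(u.classes)
        assert set(s.AV_j) == set(z.clusters)
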