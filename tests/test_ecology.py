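import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from braingut.ecology import (
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    jaccard,
    pcoa,
    permanova,
    shannon,
    within_group_dissimilarity_test,
)


class TestShannon:
    def test_uniform_four_taxa(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([0.0, 0.7, 0.0]) == 0.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.dirichlet(np.ones(rng.integers(2, 12)))
            oracle = -sum(p * np.log(p) for p in a if p > 0)
            assert shannon(a) == pytest.approx(oracle, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestDissimilarities:
    def test_bray_curtis_hand_value(self):
        # sum|x-y| = 0.4+0+0.4 = 0.8; sum(x+y) = 2 -> 0.4
        assert bray_curtis([0.6, 0.4, 0], [0.2, 0.4, 0.4]) == pytest.approx(0.4)

    def test_bray_curtis_extremes(self):
        assert bray_curtis([1, 2], [1, 2]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_jaccard_examples(self):
        assert jaccard([1, 1, 1, 0], [1, 1, 1, 0]) == 0.0
        assert jaccard([1, 0], [0, 1]) == 1.0
        # A={0,1,2}, B={1,2,3}: 2 shared of 4 -> 0.5
        assert jaccard([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            jaccard([0, 0], [0, 0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1e3, allow_nan=False), min_size=2, max_size=20),
           st.integers(0, 2**31 - 1))
    def test_symmetry_and_range_property(self, x, seed):
        y = np.random.default_rng(seed).uniform(0, 1e3, len(x))
        x = np.asarray(x)
        if (x + y).sum() == 0:
            return
        bc = bray_curtis(x, y)
        assert bc == pytest.approx(bray_curtis(y, x), abs=1e-12)
        assert 0.0 <= bc <= 1.0
        if (x > 0).any() or (y > 0).any():
            jc = jaccard(x, y)
            assert jc == pytest.approx(jaccard(y, x), abs=1e-12)
            assert 0.0 <= jc <= 1.0

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (6, 8))
        d = distance_matrix(X, [f"s{i}" for i in range(6)], "bray_curtis")
        for i in range(6):
            for j in range(i + 1, 6):
                assert d.matrix[i, j] == pytest.approx(bray_curtis(X[i], X[j]), abs=1e-12)


class TestPcoa:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           "bray_curtis")
        coords, evals = pcoa(d)
        assert evals[0] == pytest.approx(evals[1], rel=1e-9)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        D /= D.max() * 1.01
        d = DistanceMatrix([f"s{i}" for i in range(10)], D, "bray_curtis")
        coords, evals = pcoa(d)
        # Procrustes: compare centered Gram matrices (rotation-invariant)
        pts_scaled = (pts - pts.mean(0)) / (D.max() * 1.01 / np.sqrt(1))  # same scale as D
        g1 = coords[:, :2] @ coords[:, :2].T
        p = pts - pts.mean(0)
        p /= (np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max() * 1.01)
        g2 = p @ p.T
        np.testing.assert_allclose(g1, g2, atol=1e-8)

    def test_trace_identity(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (7, 5))
        d = distance_matrix(X, [f"s{i}" for i in range(7)], "bray_curtis")
        coords, evals = pcoa(d)
        n = 7
        D2 = d.matrix ** 2
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        assert evals.sum() == pytest.approx(np.trace(B), abs=1e-9)

    def test_small_matrix_errors(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]), "bray_curtis")
        with pytest.raises(ValueError):
            pcoa(d)


class TestPermanova:
    def _skbio_oracle(self, dm, groups, ids):
        import warnings
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = skbio_permanova(SkbioDM(dm, ids=ids), list(map(str, groups)),
                                  permutations=0)
        return float(res["test statistic"])

    def test_pseudo_f_matches_skbio_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(8, 16))
            X = rng.uniform(0, 1, (n, 5))
            groups = rng.choice(["a", "b", "c"], n)
            while min(np.bincount(np.unique(groups, return_inverse=True)[1])) < 2 \
                    or len(set(groups)) < 2:
                groups = rng.choice(["a", "b", "c"], n)
            ids = [f"s{i}" for i in range(n)]
            d = distance_matrix(X, ids, "bray_curtis")
            mine = permanova(d, groups, n_permutations=0, seed=0)
            oracle_f = self._skbio_oracle(d.matrix, groups, ids)
            assert mine.pseudo_f == pytest.approx(oracle_f, rel=1e-10)

    def test_r2_identity_and_relabel_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (12, 6))
        d = distance_matrix(X, [f"s{i}" for i in range(12)], "bray_curtis")
        g1 = ["a"] * 6 + ["b"] * 6
        g2 = ["zzz"] * 6 + ["aaa"] * 6
        r1 = permanova(d, g1, n_permutations=99, seed=1)
        r2 = permanova(d, g2, n_permutations=99, seed=1)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-14)
        assert 0.0 <= r1.r_squared <= 1.0

    def test_separated_clusters_min_p(self):
        rng = np.random.default_rng(8)
        a = np.array([0.8, 0.05, 0.03, 0.02]) + rng.uniform(0, 0.01, (8, 4))
        b = np.array([0.02, 0.03, 0.05, 0.8]) + rng.uniform(0, 0.01, (8, 4))
        X = np.vstack([a, b])
        d = distance_matrix(X, [f"s{i}" for i in range(16)], "bray_curtis")
        res = permanova(d, ["a"] * 8 + ["b"] * 8, n_permutations=199, seed=2)
        assert res.p_value == pytest.approx(1 / 200)

    def test_degenerate_within_zero_gives_r2_one(self):
        # two groups, identical composition within each group
        m = np.zeros((4, 4))
        m[:2, 2:] = 0.8
        m[2:, :2] = 0.8
        d = DistanceMatrix([f"s{i}" for i in range(4)], m, "bray_curtis")
        res = permanova(d, ["a", "a", "b", "b"], n_permutations=9, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_rejection_rate_calibrated_under_null(self):
        rng = np.random.default_rng(9)
        rejections = 0
        runs = 200
        for i in range(runs):
            X = rng.uniform(0, 1, (14, 5))
            d = distance_matrix(X, [f"s{i}" for i in range(14)], "bray_curtis")
            res = permanova(d, ["a"] * 7 + ["b"] * 7, n_permutations=99,
                            seed=int(rng.integers(2**31 - 1)))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / runs <= 0.08

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(10)
        pvals = []
        for i in range(500):
            X = rng.uniform(0, 1, (10, 4))
            d = distance_matrix(X, [f"s{i}" for i in range(10)], "bray_curtis")
            pvals.append(permanova(d, ["a"] * 5 + ["b"] * 5, n_permutations=199,
                                   seed=int(rng.integers(2**31 - 1))).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_group_size_preconditions(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]), "bray_curtis")
        with pytest.raises(ValueError):
            permanova(d, ["x", "x", "y"], n_permutations=9)


class TestWithinGroupDissimilarity:
    def test_identical_compositions_degenerate_p_one(self):
        X = np.tile([0.3, 0.3, 0.3], (8, 1))
        d = distance_matrix(X, [f"s{i}" for i in range(8)], "bray_curtis")
        res = within_group_dissimilarity_test(d, ["case"] * 4 + ["ctl"] * 4)
        assert res["p_value"] == 1.0

    def test_noisier_group_detected(self):
        rng = np.random.default_rng(11)
        base = np.full(20, 0.04)
        cases = np.abs(base + rng.normal(0, 0.03, (30, 20)))
        ctls = np.abs(base + rng.normal(0, 0.005, (30, 20)))
        X = np.vstack([cases, ctls])
        X = X / X.sum(axis=1, keepdims=True) * 0.9
        d = distance_matrix(X, [f"s{i}" for i in range(60)], "bray_curtis")
        groups = ["case"] * 30 + ["ctl"] * 30
        res = within_group_dissimilarity_test(d, groups)
        assert res["median_difference"] > 0
        assert res["p_value"] < 0.05

    def test_label_swap_flips_median_difference(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 0.1, (12, 10))
        d = distance_matrix(X, [f"s{i}" for i in range(12)], "bray_curtis")
        a = within_group_dissimilarity_test(d, ["case"] * 6 + ["ctl"] * 6)
        b = within_group_dissimilarity_test(d, ["ctl"] * 6 + ["case"] * 6)
        assert a["median_difference"] == pytest.approx(-b["median_difference"])
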