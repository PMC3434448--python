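import itertools
import math

import numpy as np
import pytest

import cortical_layout as cl
from cortical_layout.clustering import LeafOrder
from cortical_layout.compactness import CompactnessError


def _seq(points, labels=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:  # collinear shortcut: place on the PA axis
        points = np.column_stack([np.zeros_like(points), points, np.zeros_like(points)])
    labels = labels or [f"P{i}" for i in range(len(points))]
    return cl.LayoutSequence(labels=labels, coords=points)


def _exhaustive_perm_means(points):
    points = np.asarray(points, dtype=float)
    means = []
    for perm in itertools.permutations(range(len(points))):
        p = points[list(perm)]
        means.append(np.linalg.norm(np.diff(p, axis=0), axis=1).mean())
    return np.asarray(means)


class TestSuccessiveDistances:
    def test_52_areas_give_51_distances(self, atlas):
        order = LeafOrder(sequence=atlas.labels)
        seq = cl.LayoutSequence.from_leaf_order(order, atlas, rectify_lr=True)
        assert cl.successive_distances(seq).size == 51

    def test_hemisphere_sequence_gives_25_distances(self, atlas):
        left = atlas.subset("left")
        seq = cl.LayoutSequence.from_leaf_order(
            LeafOrder(sequence=left.labels), left, rectify_lr=False
        )
        assert cl.successive_distances(seq).size == 25

    def test_precentral_pair_rectified_distance(self, atlas):
        order = LeafOrder(sequence=["L_Precentral", "R_Precentral"])
        seq = cl.LayoutSequence.from_leaf_order(order, atlas, rectify_lr=True)
        d = cl.successive_distances(seq)
        assert d[0] == pytest.approx(math.sqrt(3.29), abs=1e-10)
        assert d[0] == pytest.approx(1.8138, abs=1e-4)

    def test_identical_consecutive_coordinates_give_zero(self):
        seq = _seq([[0, 0, 0], [0, 0, 0], [1, 1, 1]])
        assert cl.successive_distances(seq)[0] == 0.0

    def test_mean_of_equally_spaced_collinear_points(self):
        assert cl.mean_successive_distance(_seq([0.0, 1.0, 2.0])) == pytest.approx(1.0)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-40, 40, size=(9, 3))
        fwd = cl.mean_successive_distance(_seq(pts))
        rev = cl.mean_successive_distance(_seq(pts[::-1]))
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_rectified_flag_rejects_signed_lr(self):
        with pytest.raises(CompactnessError):
            cl.LayoutSequence(labels=["a", "b"], coords=[[-1, 0, 0], [1, 0, 0]],
                              rectified=True)


class TestAdjacencyTest:
    def test_three_collinear_points_match_exhaustive_oracle(self):
        # orderings of (0,1,2): means {1, 1.5, 1.5, 1.5, 1.5, 1}, grand 4/3
        seq = _seq([0.0, 1.0, 2.0])
        exact = _exhaustive_perm_means([[0, 0, 0], [0, 1, 0], [0, 2, 0]])
        assert exact.mean() == pytest.approx(4.0 / 3.0)
        res = cl.adjacency_test(seq, n_perms=20000, seed=5)
        se = exact.std(ddof=0) / math.sqrt(res.n_perms)
        assert res.d_tree == pytest.approx(1.0)
        assert res.d_perm_grand == pytest.approx(4.0 / 3.0, abs=3 * se)
        assert res.c_index == pytest.approx(4.0 / 3.0, abs=4 * se)
        assert res.violations == 0
        assert res.m == 2

    def test_worst_case_order_counts_violations(self):
        # observed (1, 3, 2): mean 1.5; 2 of 6 orderings have mean 1 < 1.5
        seq = _seq([1.0, 3.0, 2.0])
        res = cl.adjacency_test(seq, n_perms=30000, seed=2)
        assert res.d_tree == pytest.approx(1.5)
        frac = res.violations / res.n_perms
        assert frac == pytest.approx(2.0 / 6.0, abs=0.02)

    def test_monte_carlo_matches_exhaustive_for_n7(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-30, 30, size=(7, 3))
        exact = _exhaustive_perm_means(pts)
        res = cl.adjacency_test(_seq(pts), n_perms=10000, seed=3)
        se = exact.std(ddof=0) / math.sqrt(res.n_perms)
        assert res.d_perm_grand == pytest.approx(exact.mean(), abs=3 * se)

    def test_seeded_determinism(self):
        pts = np.random.default_rng(1).uniform(0, 10, size=(8, 3))
        a = cl.adjacency_test(_seq(pts), n_perms=500, seed=42)
        b = cl.adjacency_test(_seq(pts), n_perms=500, seed=42)
        assert a.to_dict() == b.to_dict()
        c = cl.adjacency_test(_seq(pts), n_perms=500, seed=43)
        assert c.to_dict() != a.to_dict()

    def test_random_observed_order_has_unit_compactness_on_average(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-40, 40, size=(16, 3))
        cs = []
        for k in range(100):
            perm = rng.permutation(16)
            res = cl.adjacency_test(_seq(pts[perm]), n_perms=500, seed=k)
            cs.append(res.c_index)
        assert 0.95 <= np.mean(cs) <= 1.05

    def test_degenerate_identical_coordinates_raise(self):
        with pytest.raises(CompactnessError, match="degenerate"):
            cl.adjacency_test(_seq([[1, 1, 1]] * 4), n_perms=10, seed=0)


class TestSubsetAnalyses:
    def test_pair_windows_have_unit_compactness_and_no_violations(self):
        pts = np.random.default_rng(3).uniform(0, 20, size=(10, 3))
        seq = _seq(pts)
        windows = cl.subset_analysis(seq, [2], n_subsets=20, n_perms=50, seed=1)
        np.testing.assert_allclose(windows["c_subset"], 1.0, atol=1e-12)
        assert windows["violations"].sum() == 0
        curve = cl.size_law_curve(seq, [2], windows=windows)
        assert curve["c_geometric_mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_length_window_reproduces_adjacency_test(self):
        pts = np.random.default_rng(4).uniform(0, 30, size=(9, 3))
        seq = _seq(pts)
        res = cl.adjacency_test(seq, n_perms=400, seed=77)
        windows = cl.subset_analysis(seq, [9], n_subsets=1, n_perms=400, seed=77)
        assert windows["c_subset"].iloc[0] == pytest.approx(res.c_index, abs=1e-12)
        assert windows["violations"].iloc[0] == res.violations
        curve = cl.size_law_curve(seq, [9], windows=windows)
        assert curve["c_geometric_mean"].iloc[0] == pytest.approx(res.c_index, abs=1e-12)

    def test_collinear_sequence_has_zero_metamodule_violations(self):
        seq = _seq(np.arange(8.0))
        table = cl.metamodule_test(seq, [3, 4, 6], n_subsets=30, n_perms=200, seed=6)
        assert (table["violations"] == 0).all()
        # exhaustive check for small windows: contiguous order is minimal
        for L in (3, 4, 6):
            for start in range(8 - L + 1):
                pts = np.column_stack([np.zeros(L), np.arange(start, start + L), np.zeros(L)])
                exact = _exhaustive_perm_means(pts)
                assert exact.min() >= (L - 1) / (L - 1) - 1e-12  # observed mean is 1

    def test_seeded_determinism_of_windows(self):
        pts = np.random.default_rng(5).uniform(0, 30, size=(12, 3))
        seq = _seq(pts)
        a = cl.subset_analysis(seq, [4, 6], n_subsets=10, n_perms=100, seed=9)
        b = cl.subset_analysis(seq, [4, 6], n_subsets=10, n_perms=100, seed=9)
        assert a.equals(b)

    def test_oversized_window_raises(self):
        seq = _seq(np.arange(5.0))
        with pytest.raises(CompactnessError, match="outside"):
            cl.subset_analysis(seq, [6], n_subsets=2, n_perms=10, seed=0)

    def test_window_starts_cover_full_range(self):
        seq = _seq(np.arange(20.0))
        windows = cl.subset_analysis(seq, [5], n_subsets=400, n_perms=1, seed=2)
        starts = windows["start"].unique()
        assert starts.min() == 0 and starts.max() == 20 - 5
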