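import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

import cortical_layout as cl
from cortical_layout.clustering import ClusteringError


def _prox(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"A{i}" for i in range(values.shape[0])]
    return cl.ProximityMatrix(labels=labels, values=values)


class TestProfileDistance:
    def test_identical_profiles_have_zero_distance(self):
        # constant off-diagonal proximity: every pair shares its profile
        P = np.full((4, 4), 2.2)
        np.fill_diagonal(P, 2.9)
        d = cl.profile_distance_matrix(_prox(P))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(d[off], 0.0, atol=1e-12)

    def test_hand_computed_two_shared_columns(self):
        # rows a, b differ by 0.1 in each of the 2 columns that are not
        # self-columns of the pair -> d = 2 * 0.1^2 = 0.02
        P = np.array(
            [
                [2.9, 2.0, 2.10, 2.20],
                [2.0, 2.9, 2.20, 2.30],
                [2.10, 2.20, 2.9, 2.0],
                [2.20, 2.30, 2.0, 2.9],
            ]
        )
        d = cl.profile_distance_matrix(_prox(P))
        assert d[0, 1] == pytest.approx(0.02, abs=1e-12)

    def test_symmetry_on_random_proximity(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(1.5, 2.5, size=(8, 8))
        P = (raw + raw.T) / 2
        d = cl.profile_distance_matrix(_prox(P))
        np.testing.assert_allclose(d, d.T, atol=0)
        assert (np.diag(d) == 0).all()

    def test_self_columns_do_not_leak(self):
        # inflating the diagonal must not change any pairwise distance
        rng = np.random.default_rng(1)
        raw = rng.uniform(1.5, 2.5, size=(6, 6))
        P = (raw + raw.T) / 2
        d0 = cl.profile_distance_matrix(_prox(P))
        P2 = P.copy()
        np.fill_diagonal(P2, 99.0)
        d1 = cl.profile_distance_matrix(_prox(P2))
        # only columns a and b of the pair differ, and those are excluded
        # for entry (a, b) -- but they ARE shared columns for other pairs
        for a in range(6):
            for b in range(6):
                if a != b:
                    contrib = sum(
                        (P[a, k] - P[b, k]) ** 2 for k in range(6) if k not in (a, b)
                    )
                    assert d0[a, b] == pytest.approx(contrib, abs=1e-10)
                    assert d1[a, b] == pytest.approx(contrib, abs=1e-10)


def _brute_force_upgma(dist):
    """Recompute every inter-cluster distance from scratch at each step."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            key = (d, i, j)
            if best is None or key < best:
                best = key
        d, i, j = best
        merges.append((i, j, d, len(clusters[i]) + len(clusters[j])))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return np.array(merges)


def _random_distance(rng, n):
    raw = rng.uniform(0.5, 4.0, size=(n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestUPGMA:
    def test_two_leaves_merge_at_their_distance(self):
        d = np.array([[0.0, 3.7], [3.7, 0.0]])
        tree = cl.upgma(d, labels=["A", "B"])
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(3.7)

    def test_three_leaf_tie_case(self):
        # (A,B) at 1, then (AB, C) at (4 + 4) / 2 = 4
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        tree = cl.upgma(d, labels=list("ABC"))
        np.testing.assert_allclose(tree.merges[:, 2], [1.0, 4.0])
        assert tuple(tree.merges[0, :2]) == (0.0, 1.0)

    def test_three_leaf_average_case(self):
        # (A,B) at 1, then (AB, C) at (2 + 4) / 2 = 3
        d = np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float)
        tree = cl.upgma(d, labels=list("ABC"))
        np.testing.assert_allclose(tree.merges[:, 2], [1.0, 3.0])

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_recomputation(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = _random_distance(rng, n)
            tree = cl.upgma(d)
            oracle = _brute_force_upgma(d)
            np.testing.assert_allclose(tree.merges[:, 2], oracle[:, 2], atol=1e-10)
            np.testing.assert_allclose(tree.merges[:, 3], oracle[:, 3])

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(99)
        for n in (5, 10, 20):
            d = _random_distance(rng, n)
            tree = cl.upgma(d)
            Z = linkage(squareform(d, checks=False), method="average")
            np.testing.assert_allclose(np.sort(tree.merges[:, 2]), np.sort(Z[:, 2]),
                                       atol=1e-10)

    def test_heights_are_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            d = _random_distance(rng, rng.integers(3, 12))
            tree = cl.upgma(d)
            heights = tree.merges[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_nan_distance_raises(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ClusteringError, match="NaN"):
            cl.upgma(d)

    def test_newick_is_parseable_and_ultrametric(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(4)
        d = _random_distance(rng, 6)
        labels = [f"L{i}" for i in range(6)]
        tree = cl.upgma(d, labels=labels)
        phylo = Phylo.read(StringIO(tree.to_newick()), "newick")
        leaves = {t.name for t in phylo.get_terminals()}
        assert leaves == set(labels)
        depths = phylo.depths()
        leaf_depths = [v for k, v in depths.items() if k.name in leaves]
        np.testing.assert_allclose(leaf_depths, leaf_depths[0], atol=1e-9)


class TestLeafOrder:
    def test_two_leaf_default_policy_uses_original_index(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = cl.upgma(d, labels=["B", "A"])
        order = cl.leaf_order(tree, policy="index", original_index={"A": 0, "B": 1})
        assert order.sequence == ["A", "B"]

    def test_policies_agree_on_leaf_set(self):
        rng = np.random.default_rng(11)
        d = _random_distance(rng, 7)
        tree = cl.upgma(d)
        seq_index = cl.leaf_order(tree, policy="index").sequence
        seq_height = cl.leaf_order(tree, policy="height").sequence
        seq_ser = cl.leaf_order(tree, policy="seriate", dist=d).sequence
        assert set(seq_index) == set(seq_height) == set(seq_ser) == set(tree.labels)

    def test_chain_tree_orders_as_the_chain(self):
        # 4 points on a line: unique nearest neighbors produce a caterpillar
        coords = np.array([0.0, 1.0, 2.1, 3.3])
        d = np.abs(coords[:, None] - coords[None, :])
        tree = cl.upgma(d, labels=list("ABCD"))
        order = cl.leaf_order(tree, policy="index")
        assert order.sequence == list("ABCD")

    def test_serial_order_ranks_start_at_one(self):
        d = _random_distance(np.random.default_rng(2), 5)
        tree = cl.upgma(d)
        order = cl.leaf_order(tree)
        ranks = sorted(order.serial_order.values())
        assert ranks == [1, 2, 3, 4, 5]
        assert order.serial_order[order.sequence[0]] == 1

    def test_seriate_never_worse_than_traversal(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = _random_distance(rng, 9)
            tree = cl.upgma(d)
            def cost(seq):
                idx = [tree.labels.index(l) for l in seq]
                return sum(d[idx[i], idx[i + 1]] for i in range(len(idx) - 1))
            c_ser = cost(cl.leaf_order(tree, policy="seriate", dist=d).sequence)
            c_idx = cost(cl.leaf_order(tree, policy="index").sequence)
            assert c_ser <= c_idx + 1e-12

    def test_seriate_orientation_follows_orient_by(self):
        d = _random_distance(np.random.default_rng(31), 6)
        tree = cl.upgma(d)
        values = np.arange(6.0)
        fwd = cl.leaf_order(tree, policy="seriate", dist=d, orient_by=values)
        rev = cl.leaf_order(tree, policy="seriate", dist=d, orient_by=-values)
        assert fwd.sequence == rev.sequence[::-1]


@pytest.fixture(scope="module")
def latent_tree(atlas):
    C = cl.ground_truth_correlation(atlas, cl.SynthConfig())
    P = 0.85 * C + 2.0
    np.fill_diagonal(P, 0.85 + 2.0)
    prox = cl.ProximityMatrix(labels=atlas.labels, values=(P + P.T) / 2)
    dist = cl.profile_distance_matrix(prox)
    return cl.upgma(dist, labels=atlas.labels), dist


class TestRecoveryOnLatentStructure:
    """Clustering the noise-free model proximity recovers the spatial layout."""

    def test_homotopic_partners_are_nearest_neighbors(self, latent_tree, atlas):
        tree, _ = latent_tree
        nearest = tree.nearest_leaf()
        hits = sum(
            atlas.stem(nearest[i]) == atlas.stem(label)
            for i, label in enumerate(atlas.labels)
        )
        assert hits / atlas.n_areas >= 0.90

    def test_serial_order_tracks_anterior_posterior_axis(self, latent_tree, atlas):
        tree, dist = latent_tree
        pa = atlas.frame["y"].to_numpy(dtype=float)
        order = cl.leaf_order(tree, policy="seriate", dist=dist, orient_by=pa)
        ranks = order.ranks(atlas.labels)
        # homotopic pairs share a PA rank: use the pair-mean PA, anterior first
        stems = np.array(atlas.stems)
        pair_pa = np.array([pa[stems == s].mean() for s in stems])
        rho = spearmanr(ranks, -pair_pa).statistic
        assert rho >= 0.8
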