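"""UPGMA dendrogram on proximity profiles and deterministic leaf orders.

Areas are clustered on the squared Euclidean distance between their
proximity-matrix rows ("connectivity profiles"), with the two self
columns of each pair excluded so an area's own (within-area) proximity
does not dominate the comparison. The linkage is UPGMA: at every step
the closest pair of clusters merges, and the distance from the merged
cluster to any other is the unweighted arithmetic mean of all cross
pairs of original elements (implemented by the size-weighted update).

UPGMA is implemented in-package because the merge tie-break must be
deterministic and documented (smallest lexicographic pair of cluster
ids); scipy's average linkage serves as an independent cross-check in
the test suite, not as the implementation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .connectivity import ProximityMatrix

__all__ = [
    "Dendrogram",
    "LeafOrder",
    "ClusteringError",
    "profile_distance_matrix",
    "upgma",
    "leaf_order",
]


class ClusteringError(ValueError):
    pass


def profile_distance_matrix(proximity: ProximityMatrix) -> np.ndarray:
    """Squared Euclidean distance between proximity rows, self-columns excluded.

    d(a, b) = sum_{k != a, b} (P[a, k] - P[b, k])^2.
    """
    P = proximity.values
    n = P.shape[0]
    full = cdist(P, P, metric="sqeuclidean")
    diag = np.diag(P)
    # remove the contribution of columns a and b from each pair
    col_a = (diag[:, None] - P.T) ** 2      # (a,b) -> (P[a,a] - P[b,a])^2
    col_b = (P - diag[None, :]) ** 2        # (a,b) -> (P[a,b] - P[b,b])^2
    d = full - col_a - col_b
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """UPGMA merge tree in scipy linkage convention.

    ``merges`` is an (n-1, 4) array; row m merges clusters ``i`` and
    ``j`` (leaves are 0..n-1, the cluster created by row m has id n+m)
    at ``height`` (squared-distance units) into a cluster of ``size``
    leaves.
    """

    merges: np.ndarray = field(repr=False)
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ClusteringError("need exactly n - 1 merges for n leaves")
        if np.any(np.diff(self.merges[:, 2]) < -1e-12):
            raise ClusteringError("UPGMA heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix (copy)."""
        return self.merges.astype(float).copy()

    def children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {
            n + m: (int(i), int(j))
            for m, (i, j, _, _) in enumerate(self.merges)
        }

    def cophenetic(self) -> np.ndarray:
        """Leaf x leaf matrix of merge heights (height of the lowest common cluster)."""
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        return squareform(cophenet(self.to_linkage()))

    def nearest_leaf(self) -> list[str]:
        """For each leaf, the label of its cophenetically closest other leaf."""
        coph = self.cophenetic()
        np.fill_diagonal(coph, np.inf)
        return [self.labels[j] for j in coph.argmin(axis=1)]

    # -- export ------------------------------------------------------------
    def to_merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_i", "cluster_j", "height", "size"])

    def to_merge_csv(self, path: str | Path) -> None:
        self.to_merge_frame().to_csv(path, index=False)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (node age = height / 2)."""
        n = self.n_leaves
        kids = self.children()
        age = {i: 0.0 for i in range(n)}
        for m, (_, _, h, _) in enumerate(self.merges):
            age[n + m] = h / 2.0

        def render(node: int, parent_age: float) -> str:
            length = parent_age - age[node]
            if node < n:
                return f"{self.labels[node]}:{length:.10g}"
            a, b = kids[node]
            return f"({render(a, age[node])},{render(b, age[node])}):{length:.10g}"

        root = 2 * n - 2
        a, b = kids[root]
        return f"({render(a, age[root])},{render(b, age[root])});"


def upgma(dist: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a square distance matrix.

    Ties in the minimum inter-cluster distance are broken by the smallest
    (i, j) cluster-id pair, so results are deterministic across runs.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if n < 2:
        raise ClusteringError("need at least 2 leaves")
    if np.isnan(dist).any():
        raise ClusteringError("NaN in distance matrix")
    if not np.allclose(dist, dist.T):
        raise ClusteringError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]

    # active clusters: id -> (row in work matrix, size)
    work = dist.astype(float).copy()
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4))
    for m in range(n - 1):
        k = len(ids)
        best = None
        for ai in range(k):
            for bi in range(ai + 1, k):
                key = (work[ai, bi], ids[ai], ids[bi])
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        (h, ci, cj), ai, bi = best
        si, sj = sizes[ci], sizes[cj]
        new_id = n + m
        merges[m] = (ci, cj, h, si + sj)
        # size-weighted update = unweighted mean over original cross pairs
        new_row = (si * work[ai] + sj * work[bi]) / (si + sj)
        keep = [x for x in range(k) if x not in (ai, bi)]
        work = np.vstack([work[keep][:, keep],
                          new_row[keep][None, :]])
        work = np.hstack([work, np.r_[new_row[keep], 0.0][:, None]])
        ids = [ids[x] for x in keep] + [new_id]
        sizes[new_id] = si + sj
    return Dendrogram(merges=merges, labels=list(labels))


@dataclass
class LeafOrder:
    """Serial order of areas read off the dendrogram, rank 1 at the top."""

    sequence: list[str]
    policy: str = "index"

    @property
    def serial_order(self) -> dict[str, int]:
        return {label: rank for rank, label in enumerate(self.sequence, start=1)}

    def ranks(self, labels: list[str]) -> np.ndarray:
        so = self.serial_order
        return np.array([so[l] for l in labels], dtype=float)

    def to_frame(self, atlas=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"rank": np.arange(1, len(self.sequence) + 1), "label": self.sequence}
        )
        if atlas is not None:
            hemi = dict(zip(atlas.labels, atlas.hemispheres))
            frame["hemisphere"] = [hemi[l] for l in self.sequence]
        return frame

    def to_csv(self, path: str | Path, atlas=None) -> None:
        self.to_frame(atlas).to_csv(path, index=False)


def _traversal_order(
    tree: Dendrogram, policy: str, original_index: dict[str, int] | None
) -> list[int]:
    n = tree.n_leaves
    kids = tree.children()
    heights = {i: 0.0 for i in range(n)}
    for m, (_, _, h, _) in enumerate(tree.merges):
        heights[n + m] = float(h)
    if original_index is None:
        leaf_rank = list(range(n))
    else:
        leaf_rank = [original_index[label] for label in tree.labels]

    @functools.lru_cache(maxsize=None)
    def min_leaf(node: int) -> int:
        if node < n:
            return leaf_rank[node]
        a, b = kids[node]
        return min(min_leaf(a), min_leaf(b))

    def key(node: int):
        if policy == "index":
            return (min_leaf(node),)
        if policy == "height":
            return (heights[node], min_leaf(node))
        raise ClusteringError(f"unknown leaf-order policy {policy!r}")

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = sorted(kids[node], key=key)
        return walk(a) + walk(b)

    return walk(2 * n - 2)


def _seriate_order(
    tree: Dendrogram, dist: np.ndarray, orient_by: np.ndarray | None
) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list, optimal_leaf_ordering
    from scipy.spatial.distance import squareform

    y = squareform(np.asarray(dist, dtype=float), checks=False)
    Z = optimal_leaf_ordering(tree.to_linkage(), y)
    order = [int(i) for i in leaves_list(Z)]
    if orient_by is not None:
        vals = np.asarray(orient_by, dtype=float)
        # top of the order = end with the larger orientation value
        if vals[order[0]] < vals[order[-1]]:
            order = order[::-1]
    elif order[0] > order[-1]:
        order = order[::-1]
    return order


def leaf_order(
    tree: Dendrogram,
    policy: str = "index",
    dist: np.ndarray | None = None,
    orient_by: np.ndarray | None = None,
    original_index: dict[str, int] | None = None,
) -> LeafOrder:
    """Deterministic serial order of leaves.

    Policies:

    * ``"index"`` (default): at each internal node the child subtree
      containing the smaller original leaf index goes first
      (``original_index`` maps label -> index in a reference ordering
      such as the atlas; defaults to the tree's own label order);
    * ``"height"``: the tighter (lower merge height) child goes first,
      ties by smaller min leaf index;
    * ``"seriate"``: optimal leaf ordering — the flip at every internal
      node is chosen to minimize the sum of distances between adjacent
      leaves (requires ``dist``, the matrix the tree was built from).
      The direction of the final order is fixed by ``orient_by`` (the
      leaf with the larger value of ``orient_by`` comes first; e.g. pass
      PA coordinates to put the anterior end on top) or, absent that, by
      placing the endpoint with the smaller original index first.
    """
    if policy == "seriate":
        if dist is None:
            raise ClusteringError("policy 'seriate' needs the distance matrix")
        order = _seriate_order(tree, dist, orient_by)
    else:
        order = _traversal_order(tree, policy, original_index)
    return LeafOrder(sequence=[tree.labels[i] for i in order], policy=policy)
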