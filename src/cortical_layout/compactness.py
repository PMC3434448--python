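"""Permutation tests of compact component placement (Cherniak's postulates).

Given the serial order of areas in the dendrogram, the observed layout
cost is the mean Euclidean distance between spatially successive areas,

    D_tree = (1 / M) * sum_i ||x_(i+1) - x_i||,   M = n - 1.

Random permutations of the placement give a null distribution of the
same mean; the compactness index

    c = mean_k(D_perm_k) / D_tree

measures the gain of the observed placement over a random one (c > 1:
compact). Three tests:

* adjacency rule — count permutations with D_perm < D_tree on the whole
  sequence (zero violations = the observed layout beats every random
  placement);
* size law — the geometric mean of c over random contiguous windows of
  size L grows with L;
* metamodule grouping — contiguous windows themselves show (near-)zero
  violations at every window size.

Bilateral analyses rectify the LR coordinate (|LR|) so left/right
homotopic doublets are spatial neighbors; per-hemisphere analyses keep
LR signed.

Randomness: one root seed; independent child streams are derived per
test and per window (``numpy`` ``SeedSequence.spawn``), so results do
not depend on execution order. Permutations are uniform over all
orderings including the identity, which produces a tie (not a
violation) under the strict inequality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .atlas import AreaAtlas
from .clustering import LeafOrder

__all__ = [
    "LayoutSequence",
    "CompactnessResult",
    "CompactnessError",
    "successive_distances",
    "mean_successive_distance",
    "adjacency_test",
    "subset_analysis",
    "size_law_curve",
    "metamodule_test",
]


class CompactnessError(ValueError):
    pass


@dataclass
class LayoutSequence:
    """Area coordinates in dendrogram serial order."""

    labels: list[str]
    coords: np.ndarray = field(repr=False)  # (n, 3): LR, PA, IS in mm
    rectified: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != self.coords.shape[0] or self.coords.shape[1] != 3:
            raise CompactnessError("coords must be (n, 3) aligned to labels")
        if len(self.labels) < 2:
            raise CompactnessError("need at least 2 areas")
        if self.rectified and (self.coords[:, 0] < 0).any():
            raise CompactnessError("rectified sequence has negative LR")

    @classmethod
    def from_leaf_order(
        cls, order: LeafOrder, atlas: AreaAtlas, rectify_lr: bool = True
    ) -> "LayoutSequence":
        idx = {l: i for i, l in enumerate(atlas.labels)}
        coords = atlas.coordinates(rectify_lr=rectify_lr)[[idx[l] for l in order.sequence]]
        return cls(labels=list(order.sequence), coords=coords, rectified=rectify_lr)

    def __len__(self) -> int:
        return len(self.labels)

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def successive_distances(seq: LayoutSequence) -> np.ndarray:
    """Euclidean distances between consecutive areas; length n - 1."""
    return np.linalg.norm(np.diff(seq.coords, axis=0), axis=1)


def mean_successive_distance(seq: LayoutSequence) -> float:
    return float(successive_distances(seq).mean())


@dataclass
class CompactnessResult:
    """Observed vs permuted mean successive distance on one sequence."""

    d_tree: float           # observed mean successive distance, mm
    d_perm_grand: float     # grand mean over permutations, mm
    c_index: float          # d_perm_grand / d_tree
    n_perms: int
    violations: int         # permutations with mean strictly below observed
    m: int                  # number of successive distances
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c_index <= 0:
            raise CompactnessError("compactness index must be positive")
        if not 0 <= self.violations <= self.n_perms:
            raise CompactnessError("violation count outside [0, n_perms]")

    def to_dict(self) -> dict:
        return {
            "d_tree": self.d_tree,
            "d_perm_grand": self.d_perm_grand,
            "c_index": self.c_index,
            "n_perms": self.n_perms,
            "violations": self.violations,
            "m": self.m,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _perm_means(
    dmat: np.ndarray, indices: np.ndarray, n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean successive distance of ``n_perms`` uniform orderings of ``indices``."""
    L = indices.size
    perms = rng.permuted(np.tile(np.arange(L), (n_perms, 1)), axis=1)
    sub = dmat[np.ix_(indices, indices)]
    return sub[perms[:, :-1], perms[:, 1:]].mean(axis=1)


def _observed_mean(dmat: np.ndarray, indices: np.ndarray) -> float:
    return float(dmat[indices[:-1], indices[1:]].mean())


def adjacency_test(seq: LayoutSequence, n_perms: int = 1000, seed: int = 0) -> CompactnessResult:
    """Whole-sequence permutation test of the adjacency rule."""
    if n_perms < 1:
        raise CompactnessError("n_perms must be >= 1")
    n = len(seq)
    dmat = seq.distance_matrix()
    indices = np.arange(n)
    d_tree = _observed_mean(dmat, indices)
    if d_tree == 0.0:
        raise CompactnessError("degenerate sequence: all coordinates identical")
    # child stream 1 mirrors the per-window streams of subset_analysis, so a
    # full-length window reproduces this test exactly
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    means = _perm_means(dmat, indices, n_perms, rng)
    d_grand = float(means.mean())
    return CompactnessResult(
        d_tree=d_tree,
        d_perm_grand=d_grand,
        c_index=d_grand / d_tree,
        n_perms=n_perms,
        violations=int((means < d_tree).sum()),
        m=n - 1,
        seed=seed,
    )


def subset_analysis(
    seq: LayoutSequence,
    subset_sizes: list[int],
    n_subsets: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed permutation analysis behind the size law and metamodule tests.

    For each window size L, ``n_subsets`` contiguous windows are drawn
    with uniformly random start positions over the full allowable range
    (0 .. n - L inclusive, with replacement). Each window's placement is
    permuted ``n_perms`` times. Returns one row per window with its
    observed mean successive distance, permutation grand mean, compactness
    ratio, and strict-violation count.
    """
    n = len(seq)
    for L in subset_sizes:
        if not 2 <= L <= n:
            raise CompactnessError(f"subset size {L} outside [2, {n}]")
    dmat = seq.distance_matrix()
    root = np.random.SeedSequence(seed)
    # stream 0 drives window starts; window k (across sizes) uses stream k + 1
    children = root.spawn(1 + len(subset_sizes) * n_subsets)
    start_rng = np.random.default_rng(children[0])
    rows = []
    stream = 1
    for L in subset_sizes:
        starts = start_rng.integers(0, n - L + 1, size=n_subsets)
        for w, s in enumerate(starts):
            indices = np.arange(s, s + L)
            d_obs = _observed_mean(dmat, indices)
            if d_obs == 0.0:
                raise CompactnessError("degenerate window: identical coordinates")
            rng = np.random.default_rng(children[stream])
            stream += 1
            means = _perm_means(dmat, indices, n_perms, rng)
            rows.append(
                {
                    "L": L,
                    "window": w,
                    "start": int(s),
                    "d_tree_subset": d_obs,
                    "d_perm_subset": float(means.mean()),
                    "c_subset": float(means.mean()) / d_obs,
                    "violations": int((means < d_obs).sum()),
                }
            )
    return pd.DataFrame(rows)


def size_law_curve(
    seq: LayoutSequence,
    subset_sizes: list[int],
    n_subsets: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Geometric mean of the window compactness ratio per subset size.

    c_subset is a ratio, so windows are averaged on the log scale and
    exponentiated. Pass a precomputed ``windows`` table (from
    :func:`subset_analysis`) to avoid resampling.
    """
    if windows is None:
        windows = subset_analysis(seq, subset_sizes, n_subsets, n_perms, seed)
    out = (
        windows.groupby("L")["c_subset"]
        .apply(lambda c: float(np.exp(np.log(c).mean())))
        .rename("c_geometric_mean")
        .reset_index()
    )
    return out


def metamodule_test(
    seq: LayoutSequence,
    subset_sizes: list[int],
    n_subsets: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Total strict-violation count per subset size (metamodule grouping)."""
    if windows is None:
        windows = subset_analysis(seq, subset_sizes, n_subsets, n_perms, seed)
    return windows.groupby("L")["violations"].sum().rename("violations").reset_index()
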