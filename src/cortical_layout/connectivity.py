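"""Aggregate voxel-pair correlations into an area x area proximity matrix.

For each pair of areas, every voxel innovation series of one area is
correlated with every voxel innovation series of the other (within an
area: all unordered distinct voxel pairs). The Pearson coefficients are
Fisher z-transformed, arithmetically averaged, transformed back, and a
constant (+2) is added so the proximity is positive; per-pair proximities
are then averaged across subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AreaAtlas
from .prewhiten import InnovationsDataset

__all__ = [
    "ProximityMatrix",
    "ConnectivityError",
    "fisher_z",
    "inverse_fisher_z",
    "area_pair_mean_correlation",
    "build_proximity",
    "CLIP",
]

CLIP = 1.0 - 1e-7  # |r| clip before atanh, keeps z finite for perfect pairs


class ConnectivityError(ValueError):
    pass


def fisher_z(r, clip: float = CLIP):
    """Fisher variance-stabilizing transform z = atanh(r).

    Correlations with |r| >= 1 are clipped to ``clip`` so that degenerate
    perfect correlations stay finite. Non-finite input raises.
    """
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ConnectivityError("correlation must be finite")
    clipped = np.clip(r, -clip, clip)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform r = tanh(z); exact round-trip with fisher_z."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean / unit norm; flags rows with zero variance."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    return centered / safe[:, None], degenerate


def area_pair_mean_correlation(
    voxels_a: np.ndarray, voxels_b: np.ndarray, same_area: bool = False
) -> tuple[float, int, int]:
    """Fisher-z pooled mean correlation between two voxel sets.

    Returns ``(mean_r, n_pairs, n_skipped)``. For ``same_area=True`` the
    two sets are the same and only unordered distinct voxel pairs enter.
    Pairs involving a zero-variance series are skipped and counted.
    """
    za, bad_a = _standardize_rows(voxels_a)
    zb, bad_b = _standardize_rows(voxels_b)
    if za.shape[1] != zb.shape[1]:
        raise ConnectivityError("voxel series lengths differ")
    r = za @ zb.T
    if same_area:
        iu = np.triu_indices(r.shape[0], k=1)
        vals = r[iu]
        good = ~(bad_a[iu[0]] | bad_b[iu[1]])
    else:
        vals = r.ravel()
        good = ~(bad_a[:, None] | bad_b[None, :]).ravel()
    n_skipped = int((~good).sum())
    vals = vals[good]
    if vals.size == 0:
        raise ConnectivityError("no valid voxel pairs")
    mean_r = float(inverse_fisher_z(np.mean(fisher_z(vals))))
    return mean_r, int(vals.size), n_skipped


@dataclass
class ProximityMatrix:
    """Symmetric area x area proximity (mean correlation + 2)."""

    labels: list[str]
    values: np.ndarray = field(repr=False)
    n_subjects: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ConnectivityError("proximity shape does not match labels")
        if not np.allclose(v, v.T):
            raise ConnectivityError("proximity matrix must be symmetric")

    @property
    def n_areas(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.to_frame().to_csv(path)
        if sidecar is not None:
            payload = {"n_subjects": self.n_subjects, **self.meta}
            Path(sidecar).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, n_subjects: int = 1) -> "ProximityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(labels=list(frame.index), values=frame.to_numpy(dtype=float),
                   n_subjects=n_subjects)


def build_proximity(
    innovations: InnovationsDataset,
    atlas: AreaAtlas | None = None,
    constant: float = 2.0,
    add_after_averaging: bool = False,
) -> ProximityMatrix:
    """Subject-averaged proximity matrix over all area pairs.

    Per subject each unordered area pair gets its Fisher-z pooled mean
    voxel-pair correlation plus ``constant``; per-subject matrices are
    then arithmetically averaged. ``add_after_averaging`` adds the
    constant once after subject averaging instead — identical by
    linearity, kept as an explicit equivalence option. The diagonal holds
    the within-area pooled correlation + constant.
    """
    atlas = atlas or innovations.atlas
    labels = atlas.labels
    n = len(labels)
    total = np.zeros((n, n))
    clip_events = 0
    skipped_pairs = 0
    for s, subj in enumerate(innovations.subjects):
        for label in labels:
            if label not in subj or subj[label].size == 0:
                raise ConnectivityError(
                    f"area {label!r} has no retained voxels in subject {s}"
                )
        mats = [subj[label] for label in labels]
        corr = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                if i == j and mats[i].shape[0] == 1:
                    # a single voxel has no distinct within-area pair
                    r, n_skip = 1.0, 0
                else:
                    r, _, n_skip = area_pair_mean_correlation(
                        mats[i], mats[j], same_area=(i == j)
                    )
                corr[i, j] = corr[j, i] = r
                skipped_pairs += n_skip
                if abs(r) >= CLIP:
                    clip_events += 1
        total += corr if add_after_averaging else corr + constant
    mean = total / innovations.n_subjects
    if add_after_averaging:
        mean = mean + constant
    mean = (mean + mean.T) / 2.0
    return ProximityMatrix(
        labels=labels,
        values=mean,
        n_subjects=innovations.n_subjects,
        meta={
            "constant": constant,
            "add_after_averaging": add_after_averaging,
            "clip_events": clip_events,
            "skipped_pairs": skipped_pairs,
            "diagonal": "within-area pooled correlation + constant",
        },
    )
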