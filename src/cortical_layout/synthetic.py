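"""Synthetic multi-subject BOLD-like voxel time series with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes about resting-state fMRI:

* raw voxel series are nonstationary and autocorrelated — each is an
  integrated (d = 1) ARMA-filtered innovation plus a subject-specific
  linear drift on a positive baseline, so an ARIMA(p, 1, q) prewhitening
  model is well specified;
* areas share a latent signal whose between-area correlation decays
  exponentially with the spatial distance between areas measured on
  hemisphere-folded coordinates (|LR|, PA, IS), is attenuated by a
  constant factor for cross-hemisphere pairs, and is lifted toward 1 for
  homotopic (same-named left/right) pairs;
* voxels of one area mix the area's latent signal with idiosyncratic
  noise, so within-area coupling is the strongest tier.

With the default parameters this reproduces the empirical ordering
within-area > homotopic > ipsilateral > contralateral coupling, and the
cross-hemisphere mirror symmetry that makes homotopic areas cluster as
doublets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import AreaAtlas

__all__ = [
    "SynthConfig",
    "RawDataset",
    "SynthesisError",
    "ground_truth_correlation",
    "simulate_dataset",
    "nearest_correlation",
]


class SynthesisError(ValueError):
    """Invalid generator configuration or degenerate latent structure."""


def _poly_ok(coefs: tuple[float, ...]) -> bool:
    """Roots of 1 - c1 z - ... - cp z^p (AR) / 1 + c1 z + ... (MA) inside test.

    Stationarity/invertibility both reduce to: roots of the characteristic
    polynomial z^p - c1 z^(p-1) - ... lie strictly inside the unit circle.
    """
    coefs = tuple(coefs)
    if not coefs:
        return True
    roots = np.roots(np.r_[1.0, -np.asarray(coefs, dtype=float)])
    return bool(np.all(np.abs(roots) < 1.0 - 1e-10))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset generator.

    Defaults are the study-like conditions used throughout the test suite:
    18 subjects, 203 volumes per voxel, and a latent spatial kernel chosen
    so the implied 52-area correlation matrix is positive definite without
    repair (checked, not assumed).
    """

    n_subjects: int = 18
    voxels_per_area: int = 10
    series_length: int = 203
    distance_decay: float = 0.05        # 1/mm, on hemisphere-folded distance
    contralateral_scale: float = 0.7    # attenuation of cross-hemisphere coupling
    homotopic_boost: float = 0.3        # convex pull of homotopic pairs toward 1
    within_area_weight: float = 0.9     # latent-signal weight inside a voxel
    noise_sd: float = 0.35              # idiosyncratic voxel noise (signal units)
    trend_slope_sd: float = 0.05        # sd of subject drift slope, units/step
    ar_coefs: tuple[float, ...] = (0.4,)
    ma_coefs: tuple[float, ...] = (0.3,)
    baseline: float = 1000.0            # raw-signal offset (keeps CV well defined)
    seed: int = 0
    repair_psd: bool = False            # nearest-correlation repair, off by default
    volume_proportional_voxels: bool = False

    def validate(self) -> None:
        if min(self.n_subjects, self.voxels_per_area, self.series_length) < 1:
            raise SynthesisError("counts must be >= 1")
        if self.distance_decay < 0:
            raise SynthesisError("distance_decay must be >= 0")
        if not 0.0 < self.contralateral_scale <= 1.0:
            raise SynthesisError("contralateral_scale must be in (0, 1]")
        if not 0.0 <= self.homotopic_boost <= 1.0:
            raise SynthesisError("homotopic_boost must be in [0, 1]")
        if not 0.0 <= self.within_area_weight <= 1.0:
            raise SynthesisError("within_area_weight must be in [0, 1]")
        if self.noise_sd < 0 or self.trend_slope_sd < 0:
            raise SynthesisError("noise_sd and trend_slope_sd must be >= 0")
        if not _poly_ok(self.ar_coefs):
            raise SynthesisError("AR polynomial is not stationary")
        if not _poly_ok(tuple(-c for c in self.ma_coefs)):
            raise SynthesisError("MA polynomial is not invertible")

    def asdict(self) -> dict:
        d = asdict(self)
        d["ar_coefs"] = list(self.ar_coefs)
        d["ma_coefs"] = list(self.ma_coefs)
        return d

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class RawDataset:
    """Per subject, per area, per voxel raw series (voxels x time)."""

    subjects: list[dict[str, np.ndarray]]
    atlas: AreaAtlas
    config: SynthConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def series_length(self) -> int:
        first = next(iter(self.subjects[0].values()))
        return first.shape[1]

    def validate(self) -> None:
        length = self.series_length
        for s, subj in enumerate(self.subjects):
            for label in self.atlas.labels:
                if label not in subj:
                    raise SynthesisError(f"subject {s} lacks area {label!r}")
            for label, mat in subj.items():
                if mat.ndim != 2 or mat.shape[1] != length:
                    raise SynthesisError(f"ragged series for {label!r}")
                if not np.isfinite(mat).all():
                    raise SynthesisError(f"non-finite values in {label!r}")

    # -- long-format interchange (subject, area, voxel, t, value) ----------
    def to_long_frame(self) -> pd.DataFrame:
        recs = []
        for s, subj in enumerate(self.subjects):
            for label in self.atlas.labels:
                mat = subj[label]
                v_idx, t_idx = np.meshgrid(
                    np.arange(mat.shape[0]), np.arange(mat.shape[1]), indexing="ij"
                )
                recs.append(
                    pd.DataFrame(
                        {
                            "subject": s,
                            "area": label,
                            "voxel": v_idx.ravel(),
                            "t": t_idx.ravel(),
                            "value": mat.ravel(),
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, atlas: AreaAtlas) -> "RawDataset":
        subjects = []
        for s, sub in frame.groupby("subject", sort=True):
            areas: dict[str, np.ndarray] = {}
            for label, block in sub.groupby("area", sort=False):
                pivot = block.pivot(index="voxel", columns="t", values="value")
                areas[label] = pivot.sort_index().to_numpy(dtype=float)
            subjects.append(areas)
        ds = cls(subjects=subjects, atlas=atlas)
        ds.validate()
        return ds

    @classmethod
    def from_csv(cls, path: str | Path, atlas: AreaAtlas) -> "RawDataset":
        return cls.from_long_frame(pd.read_csv(path), atlas)

    def checksum(self) -> str:
        """Hash of the serialized dataset (byte-for-byte reproducibility)."""
        import hashlib

        buf = io.StringIO()
        self.to_long_frame().to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def nearest_correlation(C: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (Higham 2002).

    Projects onto the PSD cone and the unit-diagonal affine set until the
    smallest eigenvalue clears ``-tol``.
    """
    Y = np.asarray(C, dtype=float).copy()
    dS = np.zeros_like(Y)
    for _ in range(max_iter):
        R = Y - dS
        w, V = np.linalg.eigh(R)
        X = (V * np.clip(w, 0.0, None)) @ V.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.linalg.eigvalsh(Y).min() > -tol:
            break
    return (Y + Y.T) / 2.0


def _latent_correlation(atlas: AreaAtlas, cfg: SynthConfig) -> np.ndarray:
    D = atlas.pairwise_distances(rectify_lr=True)
    C = np.exp(-cfg.distance_decay * D)
    hemis = atlas.hemispheres.to_numpy()
    stems = np.array(atlas.stems)
    cross = hemis[:, None] != hemis[None, :]
    homot = (stems[:, None] == stems[None, :]) & cross
    C = np.where(cross, cfg.contralateral_scale * C, C)
    C = np.where(homot, C + cfg.homotopic_boost * (1.0 - C), C)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def ground_truth_correlation(atlas: AreaAtlas, cfg: SynthConfig) -> np.ndarray:
    """Latent area-level correlation matrix implied by ``cfg``.

    This is the matrix the latent area signals are drawn from — before
    voxel noise and temporal coloring — and serves as the oracle for
    recovery tests. Raises :class:`SynthesisError` when the implied matrix
    is degenerate (all off-diagonal correlations 1) or not positive
    semi-definite; set ``cfg.repair_psd=True`` to apply a nearest
    correlation-matrix repair instead of erroring.
    """
    cfg.validate()
    C = _latent_correlation(atlas, cfg)
    off = ~np.eye(len(C), dtype=bool)
    if cfg.distance_decay == 0.0 and len(C) > 1 and np.allclose(C[off], 1.0):
        raise SynthesisError(
            "degenerate latent structure: all between-area correlations are 1 "
            "(increase distance_decay or lower contralateral_scale/homotopic_boost)"
        )
    min_eig = float(np.linalg.eigvalsh(C).min())
    if min_eig < -1e-8:
        if cfg.repair_psd:
            C = nearest_correlation(C)
        else:
            raise SynthesisError(
                f"implied latent correlation matrix is not positive semi-definite "
                f"(min eigenvalue {min_eig:.4f}); lower homotopic_boost, raise "
                f"distance_decay, or set repair_psd=True"
            )
    return C


def _voxel_counts(atlas: AreaAtlas, cfg: SynthConfig) -> np.ndarray:
    if not cfg.volume_proportional_voxels:
        return np.full(atlas.n_areas, cfg.voxels_per_area, dtype=int)
    vols = atlas.frame["volume"].to_numpy(dtype=float)
    counts = np.maximum(1, np.round(cfg.voxels_per_area * vols / vols.mean()))
    return counts.astype(int)


def simulate_dataset(atlas: AreaAtlas, cfg: SynthConfig) -> RawDataset:
    """Generate a seeded multi-subject raw dataset.

    Per subject: latent area signals are drawn i.i.d. in time from
    N(0, C) with C from :func:`ground_truth_correlation`; each voxel
    mixes its area's latent signal (weight ``within_area_weight``) with
    idiosyncratic N(0, noise_sd^2) noise; the mixture is ARMA-filtered,
    summed with a subject drift slope, integrated once (cumulative sum),
    and offset by ``baseline``. Identical configs give bit-identical
    datasets.
    """
    cfg.validate()
    C = ground_truth_correlation(atlas, cfg)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    counts = _voxel_counts(atlas, cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    T = cfg.series_length
    ar = np.r_[1.0, -np.asarray(cfg.ar_coefs, dtype=float)]
    ma = np.r_[1.0, np.asarray(cfg.ma_coefs, dtype=float)]
    subjects: list[dict[str, np.ndarray]] = []
    for _ in range(cfg.n_subjects):
        slope = rng.normal(0.0, cfg.trend_slope_sd)
        latent = rng.standard_normal((T, atlas.n_areas)) @ chol.T  # (T, areas)
        areas: dict[str, np.ndarray] = {}
        for a, label in enumerate(atlas.labels):
            nvox = counts[a]
            noise = rng.standard_normal((nvox, T)) * cfg.noise_sd
            innov = cfg.within_area_weight * latent[:, a][None, :] + noise
            colored = lfilter(ma, ar, innov, axis=1)
            areas[label] = cfg.baseline + np.cumsum(colored + slope, axis=1)
        subjects.append(areas)
    ds = RawDataset(subjects=subjects, atlas=atlas, config=cfg)
    ds.validate()
    return ds
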