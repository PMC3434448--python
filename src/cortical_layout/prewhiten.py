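"""Prewhitening of raw voxel series into white-noise innovations.

Raw resting-state BOLD series carry trends and AR/MA dependence; valid
zero-lag correlation requires removing these first. The workflow here is
trim initial volumes -> coefficient-of-variation voxel filter -> ARIMA
modeling -> residual ("innovation") series with whiteness diagnostics
(Ljung-Box and Durbin-Watson) attached.

ARIMA estimation is delegated to statsmodels. Two criteria are exposed:
``"statespace"`` (full Gaussian maximum likelihood via the Kalman filter,
the default) and ``"hannan_rissanen"`` (the regression-based Hannan-
Rissanen estimator with residuals from Kalman-filtering the fixed
parameters; much faster and adequate for whitening long AR models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RawDataset
from .atlas import AreaAtlas

__all__ = [
    "InnovationSeries",
    "InnovationsDataset",
    "CVReport",
    "PrewhitenError",
    "trim_initial_volumes",
    "cv_filter",
    "fit_innovations",
    "ljung_box_q",
    "durbin_watson",
    "prewhiten_dataset",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER = (15, 1, 1)
FALLBACK_ORDERS = ((5, 1, 1), (1, 1, 1))


class PrewhitenError(ValueError):
    """Raised for series that cannot be prewhitened as requested."""


def trim_initial_volumes(series: np.ndarray, k: int = 3) -> np.ndarray:
    """Drop the first ``k`` values (scanner equilibration volumes)."""
    series = np.asarray(series, dtype=float)
    if k < 0:
        raise PrewhitenError("k must be >= 0")
    if series.shape[-1] <= k:
        raise PrewhitenError(
            f"cannot trim {k} volumes from a length-{series.shape[-1]} series"
        )
    return series[..., k:]


@dataclass
class CVReport:
    """Outcome of the coefficient-of-variation voxel filter."""

    retained: list[int]
    removed: list[dict]  # {"voxel": index, "cv": float | None, "reason": str}
    max_cv: float

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def cv_filter(voxels: np.ndarray, max_cv: float = 0.05) -> tuple[np.ndarray, CVReport]:
    """Retain voxels whose coefficient of variation (sd/mean) is <= ``max_cv``.

    ``voxels`` is a (n_voxels, T) matrix. Voxels with non-positive mean
    have no defined CV; they are excluded with an explicit reason rather
    than silently dropped.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    retained: list[int] = []
    removed: list[dict] = []
    for v, series in enumerate(voxels):
        mean = series.mean()
        if mean <= 0:
            removed.append({"voxel": v, "cv": None, "reason": "non-positive mean"})
            continue
        cv = series.std(ddof=0) / mean
        if cv <= max_cv:
            retained.append(v)
        else:
            removed.append({"voxel": v, "cv": float(cv), "reason": f"cv {cv:.4f} > {max_cv}"})
    report = CVReport(retained=retained, removed=removed, max_cv=max_cv)
    return voxels[retained], report


def durbin_watson(residuals: np.ndarray) -> float:
    """Durbin-Watson statistic sum (e_t - e_{t-1})^2 / sum e_t^2.

    Near 2 for white residuals; near 0 under strong positive lag-1
    autocorrelation, near 4 under negative.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 2:
        raise PrewhitenError("need at least 2 residuals")
    denom = float(np.sum(residuals**2))
    if denom == 0.0:
        raise PrewhitenError("zero-variance residuals")
    from statsmodels.stats.stattools import durbin_watson as _dw

    return float(_dw(residuals))


def ljung_box_q(
    residuals: np.ndarray, n_lags: int = 20, model_df: int = 0
) -> tuple[float, float]:
    """Ljung-Box portmanteau test of residual autocorrelation.

    Q = n (n + 2) sum_{k=1..n_lags} rho_k^2 / (n - k), referred to a
    chi-square with ``n_lags - model_df`` degrees of freedom. ``model_df``
    (subtract the number of fitted ARMA parameters) defaults to 0.
    Returns ``(Q, p_value)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n_lags < 1 or n_lags >= n:
        raise PrewhitenError(f"n_lags must be in [1, {n - 1}]")
    if model_df < 0 or model_df >= n_lags:
        raise PrewhitenError("model_df must be in [0, n_lags)")
    from statsmodels.stats.diagnostic import acorr_ljungbox

    tab = acorr_ljungbox(residuals, lags=[n_lags], model_df=model_df)
    return float(tab["lb_stat"].iloc[0]), float(tab["lb_pvalue"].iloc[0])


@dataclass
class InnovationSeries:
    """Prewhitened residuals of one voxel with whiteness diagnostics.

    ``values`` has length (raw length - d): the first ``d`` residuals of
    the integrated model are dropped as diffuse-initialization artifacts.
    """

    values: np.ndarray = field(repr=False)
    model_order: tuple[int, int, int]
    ljung_box_p: float
    durbin_watson: float
    converged: bool
    method: str = "statespace"
    requested_order: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise PrewhitenError("non-finite innovations")
        if not 0.0 <= self.ljung_box_p <= 1.0:
            raise PrewhitenError("ljung_box_p outside [0, 1]")


def _default_trend(d: int, trend: str | None) -> str | None:
    if trend != "auto":
        return None if trend == "n" else trend
    return "t" if d >= 1 else "c"


def _fit_once(
    series: np.ndarray, order: tuple[int, int, int], method: str, trend: str | None
) -> tuple[np.ndarray, bool]:
    """One ARIMA fit; returns (residuals incl. first d, converged flag)."""
    from statsmodels.tsa.arima.model import ARIMA

    p, d, q = order
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if p == 0 and q == 0 and trend is None:
            resid = np.diff(series, n=d) if d else series - series.mean()
            pad = np.concatenate([np.zeros(d), resid])
            return pad, True
        model = ARIMA(series, order=order, trend=trend)
        if method == "statespace":
            res = model.fit(method="statespace")
            conv = bool(res.mle_retvals.get("converged", True))
            return np.asarray(res.resid), conv
        if method == "hannan_rissanen":
            from statsmodels.tsa.arima.estimators.hannan_rissanen import hannan_rissanen

            work = np.diff(series, n=d) if d else np.asarray(series, dtype=float)
            mean = work.mean()
            hr, _ = hannan_rissanen(work - mean, ar_order=p, ma_order=q, demean=False)
            ok = bool(hr.is_stationary and hr.is_invertible)
            if not ok:
                return np.full_like(series, np.nan), False
            params = []
            if trend is not None:
                params.append(mean)
            params.extend(hr.ar_params)
            params.extend(hr.ma_params)
            params.append(max(hr.sigma2, 1e-12))
            res = model.filter(np.asarray(params))
            return np.asarray(res.resid), True
        raise PrewhitenError(f"unknown estimation method {method!r}")


def fit_innovations(
    series: np.ndarray,
    order: tuple[int, int, int] = DEFAULT_ORDER,
    method: str = "statespace",
    trend: str | None = "auto",
    lb_lags: int = 20,
    lb_model_df: int = 0,
    fallback_orders: tuple[tuple[int, int, int], ...] = FALLBACK_ORDERS,
) -> InnovationSeries:
    """Fit an ARIMA(p, d, q) model and return its innovation series.

    ``trend="auto"`` includes a drift term when d >= 1 (a constant when
    d = 0) so that linear trends are absorbed; ``trend="n"`` disables it,
    under which an (0, 1, 0) fit returns exactly the first differences.
    On non-convergence the fit is retried at ``fallback_orders``; if all
    fail a :class:`PrewhitenError` is raised.
    """
    series = np.asarray(series, dtype=float)
    p, d, q = order
    if series.size < p + d + q + 1:
        raise PrewhitenError(
            f"series of length {series.size} too short for ARIMA{order}"
        )
    if np.ptp(series) == 0.0:
        raise PrewhitenError("constant series has no innovations")

    attempts = (order,) + tuple(o for o in fallback_orders if sum(o) < sum(order))
    last_exc: Exception | None = None
    for attempt in attempts:
        trend_a = _default_trend(attempt[1], trend)
        try:
            resid, conv = _fit_once(series, attempt, method, trend_a)
        except Exception as exc:  # numerical failure inside the backend
            last_exc = exc
            continue
        values = resid[attempt[1]:]
        if not (conv and np.isfinite(values).all()):
            continue
        _, lb_p = ljung_box_q(values, n_lags=lb_lags, model_df=lb_model_df)
        return InnovationSeries(
            values=values,
            model_order=attempt,
            ljung_box_p=lb_p,
            durbin_watson=durbin_watson(values),
            converged=attempt == order,
            method=method,
            requested_order=order,
        )
    detail = f": {last_exc}" if last_exc is not None else ""
    raise PrewhitenError(f"ARIMA estimation failed at order {order} and all fallbacks{detail}")


@dataclass
class InnovationsDataset:
    """Prewhitened voxel series per subject and area, plus diagnostics."""

    subjects: list[dict[str, np.ndarray]]  # area -> (n_retained_voxels, T - d)
    atlas: AreaAtlas
    diagnostics: pd.DataFrame  # subject, area, voxel, p, d, q, converged, lb_p, dw
    order: tuple[int, int, int]
    method: str

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def prewhiten_dataset(
    raw: RawDataset,
    order: tuple[int, int, int] = DEFAULT_ORDER,
    trim: int = 3,
    max_cv: float = 0.05,
    method: str = "statespace",
    trend: str | None = "auto",
    lb_lags: int = 20,
    lb_model_df: int = 0,
) -> InnovationsDataset:
    """Trim, CV-filter, and prewhiten every voxel of a raw dataset.

    Voxels failing the CV filter or all ARIMA fits are excluded and logged
    in the diagnostics table (column ``status``).
    """
    subjects_out: list[dict[str, np.ndarray]] = []
    rows: list[dict] = []
    for s, subj in enumerate(raw.subjects):
        areas_out: dict[str, np.ndarray] = {}
        for label in raw.atlas.labels:
            trimmed = trim_initial_volumes(subj[label], k=trim)
            kept, report = cv_filter(trimmed, max_cv=max_cv)
            for rem in report.removed:
                rows.append(
                    {"subject": s, "area": label, "voxel": rem["voxel"],
                     "status": f"cv-filtered ({rem['reason']})",
                     "p": None, "d": None, "q": None,
                     "converged": None, "lb_p": None, "dw": None}
                )
            innov_rows = []
            for v_out, v_orig in enumerate(report.retained):
                try:
                    innov = fit_innovations(
                        kept[v_out], order=order, method=method, trend=trend,
                        lb_lags=lb_lags, lb_model_df=lb_model_df,
                    )
                except PrewhitenError as exc:
                    rows.append(
                        {"subject": s, "area": label, "voxel": v_orig,
                         "status": f"excluded ({exc})",
                         "p": None, "d": None, "q": None,
                         "converged": False, "lb_p": None, "dw": None}
                    )
                    continue
                innov_rows.append(innov.values)
                rows.append(
                    {"subject": s, "area": label, "voxel": v_orig, "status": "ok",
                     "p": innov.model_order[0], "d": innov.model_order[1],
                     "q": innov.model_order[2], "converged": innov.converged,
                     "lb_p": innov.ljung_box_p, "dw": innov.durbin_watson}
                )
            if not innov_rows:
                raise PrewhitenError(
                    f"area {label!r} of subject {s} has no retained voxels"
                )
            areas_out[label] = np.vstack(innov_rows)
        subjects_out.append(areas_out)
    diagnostics = pd.DataFrame(rows)
    return InnovationsDataset(
        subjects=subjects_out, atlas=raw.atlas, diagnostics=diagnostics,
        order=order, method=method,
    )
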