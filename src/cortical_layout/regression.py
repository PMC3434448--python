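"""Regression of the dendrogram serial order on area coordinates.

Tests whether the serial position of an area in the tree follows the
spatial layout of the cortex:

    order = a + b * LR + c * PA + d * IS

with LR entering signed (homotopic left/right pairs cluster together, so
a near-zero LR coefficient is itself informative). Ordinary least
squares with two-sided t tests on the residual degrees of freedom
(n - 4) and the overall F test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AreaAtlas
from .clustering import LeafOrder

__all__ = ["RegressionResult", "RegressionError", "fit_order_on_coordinates", "predicted_order"]

_COEF_NAMES = ("intercept", "lr", "pa", "is")


class RegressionError(ValueError):
    pass


@dataclass
class RegressionResult:
    """OLS fit of serial order on (LR, PA, IS) coordinates."""

    params: dict[str, float]              # intercept, lr, pa, is
    t_stats: dict[str, float]
    p_values: dict[str, float]
    f_stat: float
    f_pvalue: float
    df: tuple[int, int]                   # (regression df, residual df)
    r_squared: float
    labels: list[str] = field(default_factory=list)
    observed: np.ndarray = field(default=None, repr=False)
    fitted: np.ndarray = field(default=None, repr=False)
    rectify_lr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise RegressionError("r_squared outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "t_stats": self.t_stats,
            "p_values": self.p_values,
            "f_stat": self.f_stat,
            "f_pvalue": self.f_pvalue,
            "df": list(self.df),
            "r_squared": self.r_squared,
            "rectify_lr": self.rectify_lr,
            "serial_order_convention": "rank 1 = top of dendrogram",
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def observed_vs_predicted(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "observed": self.observed, "predicted": self.fitted}
        )


def _design(order: LeafOrder, atlas: AreaAtlas, rectify_lr: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    missing = [l for l in order.sequence if l not in set(atlas.labels)]
    if missing:
        raise RegressionError(f"ordered labels missing from atlas: {missing}")
    labels = order.sequence
    idx = {l: i for i, l in enumerate(atlas.labels)}
    coords = atlas.coordinates(rectify_lr=rectify_lr)[[idx[l] for l in labels]]
    y = np.arange(1, len(labels) + 1, dtype=float)
    return y, coords, labels


def fit_order_on_coordinates(
    order: LeafOrder, atlas: AreaAtlas, rectify_lr: bool = False
) -> RegressionResult:
    """OLS of serial order (1..n, rank 1 at the tree top) on LR, PA, IS."""
    y, coords, labels = _design(order, atlas, rectify_lr)
    n = len(y)
    if n < 5:
        raise RegressionError("need at least 5 areas for 3 predictors + intercept")
    X = np.column_stack([np.ones(n), coords])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RegressionError("collinear coordinates: design matrix is rank deficient")

    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    params = dict(zip(_COEF_NAMES, map(float, res.params)))
    t_stats = dict(zip(_COEF_NAMES, map(float, res.tvalues)))
    p_values = dict(zip(_COEF_NAMES, map(float, res.pvalues)))
    return RegressionResult(
        params=params,
        t_stats=t_stats,
        p_values=p_values,
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df=(int(res.df_model), int(res.df_resid)),
        r_squared=float(res.rsquared),
        labels=labels,
        observed=y,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        rectify_lr=rectify_lr,
    )


def predicted_order(result: RegressionResult, atlas: AreaAtlas) -> pd.Series:
    """Fitted serial order for every atlas area under the fitted coefficients."""
    coords = atlas.coordinates(rectify_lr=result.rectify_lr)
    beta = np.array([result.params[k] for k in _COEF_NAMES])
    values = np.column_stack([np.ones(len(coords)), coords]) @ beta
    return pd.Series(values, index=atlas.labels, name="predicted_order")
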