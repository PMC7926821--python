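"""GM(1,1) grey forecasting of short annual series, with an OLS baseline.

The grey model GM(1,1) targets exactly the situation of an accident
surveillance series: a short (n ~ 10), strictly positive sequence with no
usable covariates.  The original series x0 is smoothed by the first-order
accumulated generating operation (1-AGO, a cumulative sum) into x1, which is
assumed to follow the whitening ODE

    dx/dt + a * x = b,

with development coefficient ``a`` (negative a = growth) and grey input
``b``.  Discretizing with background values z1(k) = (x1(k) + x1(k-1)) / 2
gives n-1 linear equations x0(k) = -a * z1(k) + b, solved by least squares.
The restored (IAGO) prediction is

    x0_hat(k+1) = (1 - e^a) * (x0(1) - b/a) * e^(-a k),   k >= 1,

with x0_hat(1) = x0(1) by the initial-condition convention.  A model is
accepted for forecasting when the mean relative error of its in-sample fit
is below 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GreyModel", "LinearFit", "ForecastReport", "ModelComparison",
    "ago", "iago", "fit_gm11", "predict_gm11", "relative_errors",
    "fit_linear_trend", "compare_models",
]

#: |a| below this is treated as the a -> 0 (constant-series) limit.
_A_TOL = 1e-12

#: Acceptance threshold on the mean relative error.
DEFAULT_MRE_THRESHOLD = 0.20


def ago(series) -> np.ndarray:
    """First-order accumulated generating operation: running sums."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return np.cumsum(x)


def iago(series) -> np.ndarray:
    """Inverse AGO: first differences with the first element preserved."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return np.concatenate([x[:1], np.diff(x)])


@dataclass
class GreyModel:
    """Fitted GM(1,1) state."""

    x0: np.ndarray                #: original series
    x1: np.ndarray                #: 1-AGO series
    z1: np.ndarray                #: background values, k = 2..n
    a: float                      #: development coefficient (1/step)
    b: float                      #: grey input (series units / step)
    driving_coefficient: float    #: (1 - e^a)(x0(1) - b/a); scales e^(-a k)
    fitted: np.ndarray = field(default=None)  # in-sample restored values

    @property
    def n(self) -> int:
        return len(self.x0)

    def predict(self, horizon: int = 0) -> np.ndarray:
        return predict_gm11(self, horizon)


def fit_gm11(series) -> GreyModel:
    """Fit GM(1,1) by least squares on the background-value equations.

    Requires a strictly positive series of length >= 4 (the model is a
    log-growth law; non-positive values break the AGO quasi-exponential
    assumption).  The a -> 0 limit (flat series) is handled explicitly: the
    restored values then all equal ``b``.
    """
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or len(x0) < 4:
        raise ValueError("need a 1-D series with at least 4 observations")
    if (x0 <= 0).any():
        raise ValueError("GM(1,1) requires strictly positive values")

    x1 = ago(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    design = np.column_stack([-z1, np.ones_like(z1)])
    (a, b), *_ = np.linalg.lstsq(design, x0[1:], rcond=None)
    a, b = float(a), float(b)

    if abs(a) < _A_TOL:
        driving = b
    else:
        driving = (1.0 - np.exp(a)) * (x0[0] - b / a)
    model = GreyModel(x0=x0, x1=x1, z1=z1, a=a, b=b, driving_coefficient=float(driving))
    model.fitted = predict_gm11(model, horizon=0)
    return model


def predict_gm11(model: GreyModel, horizon: int = 1) -> np.ndarray:
    """Restored-series values for observations 1..n+horizon.

    The first value is x0(1); observation k+1 is driving_coefficient *
    e^(-a k).  A forecast for calendar step n+j therefore uses exponent
    index n-1+j.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    k = np.arange(1, model.n + horizon)
    if abs(model.a) < _A_TOL:
        tail = np.full(len(k), model.b)
    else:
        tail = model.driving_coefficient * np.exp(-model.a * k)
    return np.concatenate([[model.x0[0]], tail])


@dataclass
class ForecastReport:
    """Per-point relative errors of an in-sample fit plus horizon forecasts."""

    errors: np.ndarray            #: |actual - fitted| / actual, one per point
    mean_relative_error: float    #: average over all n points
    valid: bool                   #: mean relative error below threshold
    threshold: float
    forecasts: np.ndarray | None = None


def relative_errors(actual, fitted, threshold: float = DEFAULT_MRE_THRESHOLD,
                    forecasts=None) -> ForecastReport:
    """Elementwise |actual - fitted| / actual and their mean.

    The mean runs over *all* points, including a structurally exact first
    point (the GM initial condition), matching the usual grey-model error
    convention.
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if a.shape != f.shape:
        raise ValueError("actual and fitted must have equal length")
    if (a == 0).any():
        raise ValueError("relative error undefined for zero actual values")
    errors = np.abs(a - f) / np.abs(a)
    mre = float(errors.mean())
    return ForecastReport(errors, mre, mre < threshold, threshold,
                          None if forecasts is None else np.asarray(forecasts, float))


@dataclass
class LinearFit:
    """Ordinary least squares of the series on the time index t = 1..n."""

    slope: float
    intercept: float
    r_squared: float
    fitted: np.ndarray

    @property
    def n(self) -> int:
        return len(self.fitted)

    def predict(self, horizon: int = 0) -> np.ndarray:
        t = np.arange(1, self.n + horizon + 1)
        return self.slope * t + self.intercept


def fit_linear_trend(series) -> LinearFit:
    """Simple linear regression baseline against t = 1..n."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D series with at least 3 observations")
    t = np.arange(1, len(x) + 1)
    res = stats.linregress(t, x)
    fitted = res.slope * t + res.intercept
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), fitted)


@dataclass
class ModelComparison:
    """Side-by-side GM(1,1) vs linear-trend report for one series."""

    grey: GreyModel
    linear: LinearFit
    grey_report: ForecastReport
    linear_report: ForecastReport
    table: pd.DataFrame

    @property
    def preferred(self) -> str:
        return ("gm11" if self.grey_report.mean_relative_error
                <= self.linear_report.mean_relative_error else "linear")


def compare_models(series, horizon: int = 1,
                   threshold: float = DEFAULT_MRE_THRESHOLD) -> ModelComparison:
    """Fit both models and assemble the comparison table.

    The table has one row per observation with both fitted series and both
    relative-error columns (as fractions); horizon forecasts are carried on
    the two reports.
    """
    x = np.asarray(series, dtype=float)
    gm = fit_gm11(x)
    lin = fit_linear_trend(x)
    gm_all = predict_gm11(gm, horizon)
    lin_all = lin.predict(horizon)
    gm_rep = relative_errors(x, gm_all[: len(x)], threshold, forecasts=gm_all[len(x):])
    lin_rep = relative_errors(x, lin_all[: len(x)], threshold, forecasts=lin_all[len(x):])
    table = pd.DataFrame(
        {
            "actual": x,
            "gm11_fitted": gm_all[: len(x)],
            "gm11_rel_error": gm_rep.errors,
            "linear_fitted": lin_all[: len(x)],
            "linear_rel_error": lin_rep.errors,
        },
        index=pd.RangeIndex(1, len(x) + 1, name="t"),
    )
    return ModelComparison(gm, lin, gm_rep, lin_rep, table)
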