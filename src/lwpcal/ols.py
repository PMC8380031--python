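"""Ordinary least squares with a common y-uncertainty.

The first of the two calibration methods: fit LWP = m * NDVI + c assuming a
single unknown uncertainty common to all LWP means and negligible NDVI
error.  Coefficient uncertainties follow the classical Taylor error
propagation for a straight-line fit: with Delta = n*Sum(x^2) - (Sum x)^2 and
sigma_y^2 = Sum(residual^2)/(n-2),

    dm = sigma_y * sqrt(n / Delta),    dc = sigma_y * sqrt(Sum(x^2) / Delta).

The maximum relative error of a predicted LWP at a reference point
(x_ref, y_ref) is the propagated bound (|x_ref|*dm + dc) / |y_ref|,
conventionally evaluated at the dataset means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ingest import RegressionDataset


@dataclass
class FitResult:
    """Outcome of a straight-line calibration fit y = m*x + c.

    ``dm``/``dc`` are one-standard-error uncertainties of slope and
    intercept.  ``r_squared``/``p_slope`` are populated by the OLS fitter;
    ``s_weighted`` (weighted residual sum S at the solution) and
    ``adjusted_points`` (the on-line (X_i, Y_i) closest to each observation
    in the weighted metric) by the WLS fitter.  ``rel_pred_error`` is the
    propagated maximum relative prediction error at the dataset means.
    """

    method: str
    m: float
    c: float
    dm: float
    dc: float
    n: int
    label: str = ""
    r_squared: float | None = None
    p_slope: float | None = None
    sigma_y: float | None = None
    s_weighted: float | None = None
    adjusted_points: np.ndarray | None = field(default=None, repr=False)
    rel_pred_error: float | None = None
    x_mean: float | None = None
    y_mean: float | None = None


def fit_ols(data: RegressionDataset) -> FitResult:
    """Closed-form unweighted least-squares fit with Taylor uncertainties.

    Requires n >= 3 (two degrees of freedom are spent on m and c) and a
    non-degenerate spread in x.  The slope p-value uses the t statistic
    m/dm with n-2 degrees of freedom.
    """
    x, y = data.x, data.y
    n = len(data)
    if n < 3:
        raise ValueError("OLS needs at least 3 points to report uncertainties")
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    delta = n * sxx - sx * sx
    if delta <= 0 or np.isclose(delta, 0.0, atol=1e-300):
        raise ValueError("all x values equal; slope is undefined")
    m = (n * sxy - sx * sy) / delta
    c = (sy * sxx - sx * sxy) / delta
    resid = y - m * x - c
    ss_res = float((resid ** 2).sum())
    sigma_y = np.sqrt(ss_res / (n - 2))
    dm = float(sigma_y * np.sqrt(n / delta))
    dc = float(sigma_y * np.sqrt(sxx / delta))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if dm > 0:
        p_slope = float(2 * stats.t.sf(abs(m) / dm, df=n - 2))
    else:
        p_slope = 0.0  # exactly collinear data: slope determined exactly
    fit = FitResult(method="OLS", m=float(m), c=float(c), dm=dm, dc=dc, n=n,
                    label=data.label, r_squared=float(r_squared),
                    p_slope=p_slope, sigma_y=float(sigma_y),
                    x_mean=float(x.mean()), y_mean=float(y.mean()))
    if fit.y_mean != 0:
        fit.rel_pred_error = relative_prediction_error(fit)
    return fit


def relative_prediction_error(fit: FitResult,
                              x_ref: float | None = None,
                              y_ref: float | None = None) -> float:
    """Maximum relative error of a predicted LWP: (|x|*dm + dc) / |y|.

    Defaults to the dataset means stored on the fit; pass ``x_ref``/``y_ref``
    for a pointwise bound.  ``y_ref`` must be non-zero.
    """
    x_ref = fit.x_mean if x_ref is None else x_ref
    y_ref = fit.y_mean if y_ref is None else y_ref
    if x_ref is None or y_ref is None:
        raise ValueError("reference point required (fit carries no means)")
    if y_ref == 0:
        raise ValueError("relative error undefined at y_ref = 0")
    return float((abs(x_ref) * fit.dm + fit.dc) / abs(y_ref))
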