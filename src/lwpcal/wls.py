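"""Weighted least squares with measurement errors in both coordinates.

York/Williamson errors-in-variables straight-line fit: each point carries
independent uncertainties delta(x_i) and delta(y_i), turned into weights
w(x_i) = 1/delta(x_i)^2, w(y_i) = 1/delta(y_i)^2.  The fit minimises

    S = Sum_i Z_i * (y_i - m*x_i - c)^2,

where Z_i = w(x_i) w(y_i) / (m^2 w(y_i) + w(x_i)) is the per-point overall
weight merging both coordinate uncertainties.  Stationarity of S in m gives
a "least-squares cubic" g(m) = 0 whose coefficients themselves depend on m
through Z_i, so the root is found iteratively from an unweighted
least-squares seed.  The intercept is the Z-weighted centroid relation
c = <y>_Z - m <x>_Z.

Coefficient variances follow the corrected small-error propagation

    dm^2 = S/(N-2) * Sum_i [ (dm/dy_i)^2 / w(y_i) + (dm/dx_i)^2 / w(x_i) ]

(and identically for c), with the solver derivatives dm/dx_i, dm/dy_i
computed by central finite differences of the full solver, evaluated either
at the observed points or at the adjusted points (default), the two
conventions exposed as ``eval_at``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import brentq

from .ingest import RegressionDataset
from .ols import FitResult, fit_ols, relative_prediction_error

logger = logging.getLogger("lwpcal")

#: |Delta m| convergence tolerance (relative), and iteration cap, for the
#: slope refinement used inside the finite-difference derivative loop.
SLOPE_TOL = 1e-12
MAX_ITER = 200

#: Zero or missing uncertainties are floored at this fraction of the
#: coordinate range -- an exactly-zero delta would give an infinite weight.
UNCERTAINTY_FLOOR_FRAC = 1e-9


def overall_weight(wx, wy, m):
    """Overall weight Z = wx*wy / (m^2*wy + wx) for one point (or arrays).

    Limits behave as expected: wx -> inf (error-free x) gives Z -> wy,
    ordinary y-weighting; m = 0 gives Z = wy.
    """
    wx = np.asarray(wx, dtype=float)
    wy = np.asarray(wy, dtype=float)
    if np.any(wx <= 0) or np.any(wy <= 0):
        raise ValueError("weights must be positive")
    z = wx * wy / (m * m * wy + wx)
    return float(z) if z.ndim == 0 else z


def _g(m: float, x, y, wx, wy) -> float:
    """Least-squares cubic residual at slope m (Z, U, V recomputed at m)."""
    z = wx * wy / (m * m * wy + wx)
    sz = z.sum()
    u = x - (z * x).sum() / sz
    v = y - (z * y).sum() / sz
    z2 = z * z
    a = (z2 * u * u / wx).sum()
    b = (z2 * u * v / wx).sum()
    cc = (z * u * u).sum() - (z2 * v * v / wx).sum()
    d = (z * u * v).sum()
    return m ** 3 * a - 2 * m * m * b - m * cc + d


def _intercept(m: float, x, y, wx, wy) -> float:
    z = wx * wy / (m * m * wy + wx)
    sz = z.sum()
    return float((z * y).sum() / sz - m * (z * x).sum() / sz)


def _s_value(m: float, x, y, wx, wy, c: float | None = None) -> float:
    z = wx * wy / (m * m * wy + wx)
    if c is None:
        c = _intercept(m, x, y, wx, wy)
    r = y - m * x - c
    return float((z * r * r).sum())


def cubic_residual(m: float, data: RegressionDataset) -> float:
    """Public evaluation of the least-squares cubic g(m) on a dataset.

    A root of g is a candidate best slope.  Uses floored weights as the
    fitter does.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 points")
    wx, wy = _weights(data)
    return _g(m, data.x, data.y, wx, wy)


def _weights(data: RegressionDataset) -> tuple[np.ndarray, np.ndarray]:
    if data.ols_only:
        raise ValueError(
            "dataset has missing uncertainties; WLS requires dx and dy "
            "for every point (supply a dx policy upstream)")

    def floored(delta: np.ndarray, coord: np.ndarray, name: str) -> np.ndarray:
        rng = float(coord.max() - coord.min())
        floor = UNCERTAINTY_FLOOR_FRAC * (rng if rng > 0 else max(1.0, float(np.abs(coord).max())))
        out = delta.copy()
        zero = out < floor
        if zero.any():
            logger.warning("%d zero/near-zero %s uncertainties floored at %g",
                           int(zero.sum()), name, floor)
            out[zero] = floor
        return out

    dx = floored(data.dx, data.x, "x")
    dy = floored(data.dy, data.y, "y")
    return 1.0 / dx ** 2, 1.0 / dy ** 2


def _solve_slope(x, y, wx, wy, m_seed: float) -> float:
    """Root of g(m) nearest the seed, by bracket expansion + Brent.

    If several roots fall in the examined range the one with the smallest S
    is returned (with a warning).  If no sign change is found the slope is
    taken from a dense scan of S(m) refined by golden-section, since the
    minimiser of S is what the root characterises.
    """
    scale = max(abs(m_seed), (y.max() - y.min()) / max(x.max() - x.min(), 1e-12), 1e-3)
    g0 = _g(m_seed, x, y, wx, wy)
    if g0 == 0.0:
        return m_seed
    # expand a bracket geometrically around the seed, scanning the interior:
    # g is cubic-like and can hold several roots strictly inside a bracket
    # whose endpoints share a sign
    step = 0.25 * scale
    for _ in range(25):
        lo, hi = m_seed - step, m_seed + step
        roots = _bracketed_roots(lo, hi, x, y, wx, wy)
        if roots:
            return _pick_root(roots, x, y, wx, wy)
        step *= 2.0
    # fall back: dense scan of S over the widest bracket examined
    grid = np.linspace(m_seed - step, m_seed + step, 2001)
    svals = [_s_value(m, x, y, wx, wy) for m in grid]
    k = int(np.argmin(svals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda m: _s_value(m, x, y, wx, wy),
                          bracket=None, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-14})
    if not res.success:
        raise RuntimeError("WLS slope search failed; S-scan diagnostic "
                           f"minimum near m={grid[k]:.6g}")
    return float(res.x)


def _bracketed_roots(lo: float, hi: float, x, y, wx, wy, n_grid: int = 64) -> list[float]:
    grid = np.linspace(lo, hi, n_grid)
    gv = np.array([_g(m, x, y, wx, wy) for m in grid])
    roots = []
    for a, b, ga, gb in zip(grid[:-1], grid[1:], gv[:-1], gv[1:]):
        if ga == 0.0:
            roots.append(float(a))
        elif np.sign(ga) != np.sign(gb):
            roots.append(float(brentq(_g, a, b, args=(x, y, wx, wy),
                                      xtol=1e-15, rtol=8.9e-16, maxiter=MAX_ITER)))
    if gv[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def _pick_root(roots: list[float], x, y, wx, wy) -> float:
    if not roots:
        raise RuntimeError("bracket reported a sign change but no root found")
    if len(roots) == 1:
        return roots[0]
    svals = [_s_value(m, x, y, wx, wy) for m in roots]
    logger.warning("least-squares cubic has %d roots in bracket; choosing "
                   "the one with minimal S", len(roots))
    return roots[int(np.argmin(svals))]


def _refine_slope(x, y, wx, wy, m0: float, gprime: float) -> float:
    """Newton refinement of g(m)=0 from an excellent initial guess.

    Used for the finite-difference derivative solves, where the perturbed
    root lies within ~1e-6 of the base root; ``gprime`` is dg/dm at the base
    solution and is reused across iterations.  Falls back to the robust
    solver if it fails to settle.
    """
    m = m0
    for _ in range(30):
        gm = _g(m, x, y, wx, wy)
        if gprime == 0.0:
            break
        step = gm / gprime
        m -= step
        if abs(step) <= SLOPE_TOL * (1.0 + abs(m)):
            return m
    return _solve_slope(x, y, wx, wy, m0)


def fit_wls(data: RegressionDataset, eval_at: str = "adjusted") -> FitResult:
    """Errors-in-both-coordinates straight-line fit.

    Solves the least-squares cubic for the slope starting from the
    unweighted OLS seed, computes the intercept from the Z-weighted
    centroid, the adjusted points (which lie exactly on the fitted line),
    the weighted residual sum S, and coefficient uncertainties via
    finite-difference solver derivatives evaluated at the observed or
    adjusted points (``eval_at``, default "adjusted").
    """
    if eval_at not in ("observed", "adjusted"):
        raise ValueError("eval_at must be 'observed' or 'adjusted'")
    n = len(data)
    if n < 3:
        raise ValueError("WLS needs at least 3 points")
    x, y = data.x, data.y
    wx, wy = _weights(data)

    m_seed = fit_ols(data).m if n >= 3 else 0.0
    m = _solve_slope(x, y, wx, wy, m_seed)
    c = _intercept(m, x, y, wx, wy)

    z = overall_weight(wx, wy, m)
    r = y - m * x - c
    s = float((z * r * r).sum())
    x_adj = x + m * z * r / wx
    y_adj = y - z * r / wy

    # derivative base: observed or adjusted configuration.  The adjusted
    # points are exactly collinear with slope m, so m solves g = 0 there too.
    bx, by = (x_adj, y_adj) if eval_at == "adjusted" else (x, y)
    m_base = m
    # dg/dm at the base solution, reused by the Newton refinements
    h_m = 1e-7 * (1.0 + abs(m_base))
    gprime = (_g(m_base + h_m, bx, by, wx, wy)
              - _g(m_base - h_m, bx, by, wx, wy)) / (2 * h_m)

    dm_dx = np.empty(n)
    dm_dy = np.empty(n)
    dc_dx = np.empty(n)
    dc_dy = np.empty(n)
    dx_f = 1.0 / np.sqrt(wx)
    dy_f = 1.0 / np.sqrt(wy)
    for i in range(n):
        hx = 1e-6 * dx_f[i]
        xp = bx.copy(); xp[i] += hx
        xm_ = bx.copy(); xm_[i] -= hx
        m_p = _refine_slope(xp, by, wx, wy, m_base, gprime)
        m_m = _refine_slope(xm_, by, wx, wy, m_base, gprime)
        dm_dx[i] = (m_p - m_m) / (2 * hx)
        dc_dx[i] = (_intercept(m_p, xp, by, wx, wy)
                    - _intercept(m_m, xm_, by, wx, wy)) / (2 * hx)

        hy = 1e-6 * dy_f[i]
        yp = by.copy(); yp[i] += hy
        ym_ = by.copy(); ym_[i] -= hy
        m_p = _refine_slope(bx, yp, wx, wy, m_base, gprime)
        m_m = _refine_slope(bx, ym_, wx, wy, m_base, gprime)
        dm_dy[i] = (m_p - m_m) / (2 * hy)
        dc_dy[i] = (_intercept(m_p, bx, yp, wx, wy)
                    - _intercept(m_m, bx, ym_, wx, wy)) / (2 * hy)

    prefac = s / (n - 2)
    dm = float(np.sqrt(prefac * ((dm_dy ** 2 / wy) + (dm_dx ** 2 / wx)).sum()))
    dc = float(np.sqrt(prefac * ((dc_dy ** 2 / wy) + (dc_dx ** 2 / wx)).sum()))

    fit = FitResult(method="WLS", m=float(m), c=float(c), dm=dm, dc=dc, n=n,
                    label=data.label, s_weighted=s,
                    adjusted_points=np.column_stack([x_adj, y_adj]),
                    x_mean=float(x.mean()), y_mean=float(y.mean()))
    if fit.y_mean != 0:
        fit.rel_pred_error = relative_prediction_error(fit)
    return fit
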