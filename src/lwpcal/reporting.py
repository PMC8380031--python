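"""Uncertainty summaries and consolidated results tables.

Two diagnostics accompany the coefficient tables: percent coefficient
errors (100*dm/|m|, 100*dc/|c|), which compare how the two fitting methods
size their uncertainties, and the uncertainty-to-range ratio, a
signal-to-noise measure expressing a variable's typical replicate SEM as a
percentage of the span of its group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ols import FitResult

logger = logging.getLogger("lwpcal")


@dataclass
class UncertaintySummary:
    label: str
    pct_dm: float
    pct_dc: float
    ndvi_ratio: float | None = None
    lwp_ratio: float | None = None
    rel_pred_error: float | None = None


def percent_coefficient_errors(fit: FitResult) -> tuple[float, float]:
    """(100*dm/|m|, 100*dc/|c|); rejects fits with a zero coefficient."""
    if fit.m == 0 or fit.c == 0:
        raise ValueError("percent errors undefined for zero coefficients")
    return 100.0 * fit.dm / abs(fit.m), 100.0 * fit.dc / abs(fit.c)


def uncertainty_range_ratio(uncertainties: Sequence[float],
                            means: Sequence[float],
                            summary: str = "mean") -> float:
    """Typical per-group uncertainty as a percent of the range of means.

    100 * central(delta) / (max(means) - min(means)).  The central summary
    of the per-group SEMs is their arithmetic mean by default; "median" and
    "pooled" (root mean square) are selectable, and the choice is logged
    since it is a reporting convention, not a measured quantity.
    """
    d = np.asarray(list(uncertainties), dtype=float)
    v = np.asarray(list(means), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two group means to form a range")
    rng = float(v.max() - v.min())
    if rng == 0:
        raise ValueError("zero range of means: ratio undefined")
    if summary == "mean":
        central = float(d.mean())
    elif summary == "median":
        central = float(np.median(d))
    elif summary == "pooled":
        central = float(np.sqrt((d ** 2).mean()))
    else:
        raise ValueError(f"unknown summary {summary!r}")
    logger.debug("uncertainty-to-range ratio uses %s of group SEMs", summary)
    return 100.0 * central / rng


def uncertainty_summary(fit: FitResult, data) -> UncertaintySummary:
    """Assemble the per-dataset uncertainty diagnostics for one fit.

    ``data`` is the RegressionDataset the fit was computed from; its SEM
    columns feed the NDVI and LWP uncertainty-to-range ratios.
    """
    pct_dm, pct_dc = percent_coefficient_errors(fit)
    def ratio(d, v):
        try:
            return uncertainty_range_ratio(d, v)
        except ValueError:
            return None
    finite_dx = data.dx[~np.isnan(data.dx)]
    return UncertaintySummary(
        label=fit.label or data.label,
        pct_dm=pct_dm, pct_dc=pct_dc,
        ndvi_ratio=(ratio(finite_dx, data.x) if finite_dx.size == len(data)
                    else None),
        lwp_ratio=ratio(data.dy, data.y),
        rel_pred_error=fit.rel_pred_error)


def results_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Full-precision consolidated coefficient table, one row per fit."""
    rows = []
    for f in fits:
        rows.append({
            "label": f.label, "method": f.method, "n": f.n,
            "m": f.m, "dm": f.dm, "c": f.c, "dc": f.dc,
            "rel_pred_error": f.rel_pred_error,
            "r_squared": f.r_squared, "p_slope": f.p_slope,
        })
    return pd.DataFrame(rows, columns=["label", "method", "n", "m", "dm",
                                       "c", "dc", "rel_pred_error",
                                       "r_squared", "p_slope"])


def _fmt(v, nd=2):
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) \
        else f"{v:.{nd}f}"


def render_results_text(fits: Iterable[FitResult]) -> str:
    """Aligned-text rendering: label, n, m (dm), c (dc), dY/Y.

    Coefficients are displayed to two decimals; the CSV written by
    :func:`write_results_table` keeps full precision.
    """
    header = ["label", "method", "n", "m (dm)", "c (dc)", "dY/Y"]
    body = []
    for f in fits:
        body.append([
            f.label or "-", f.method, str(f.n),
            f"{_fmt(f.m)} ({_fmt(f.dm)})",
            f"{_fmt(f.c)} ({_fmt(f.dc)})",
            _fmt(f.rel_pred_error),
        ])
    widths = [max(len(r[i]) for r in [header] + body) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines.append("  ".join("-" * w for w in widths))
    for r in body:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)))
    return "\n".join(lines) + "\n"


def write_results_table(fits: Sequence[FitResult], out_dir) -> tuple[Path, Path]:
    """Emit results.csv (full precision) and results.txt (display rounding)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "results.csv"
    txt_path = out / "results.txt"
    results_frame(fits).to_csv(csv_path, index=False)
    txt_path.write_text(render_results_text(fits))
    return csv_path, txt_path
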