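"""Replicate-count resampling study.

How much does shrinking the leaf-water-potential sample size inflate the
uncertainty of the calibration coefficients?  The study draws, per
observation group, k (2 or 3) LWP readings with replacement from the
original 4-6, recomputes group means/SEMs, refits by OLS and/or WLS while
keeping the NDVI side untouched, repeats for n_sets resample sets, and
compares each coefficient quantity (m, c, dm, dc) against the
full-replicate reference fit with a one-sample t-test.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ingest import ObservationGroup, build_regression_dataset
from .ols import FitResult, fit_ols, relative_prediction_error
from .wls import fit_wls

logger = logging.getLogger("lwpcal")

QUANTITIES = ("m", "c", "dm", "dc")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def one_sample_ttest(values, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test of mean(values) against mu0.

    t = (mean - mu0) / (sd / sqrt(n)) with n-1 degrees of freedom.  A
    zero-spread sample is degenerate: if its mean equals mu0 the test is
    vacuous (t = 0, p = 1, flagged); otherwise the statistic is undefined
    and the call is rejected.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("t-test needs at least 2 values")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0:
        if mean == mu0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        raise ValueError("zero sample spread with mean != mu0: t undefined")
    t = float((mean - mu0) / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, df=n - 1, p=p)


def draw_resamples(groups: list[ObservationGroup], k: int, n_sets: int,
                   seed: int) -> list[list[ObservationGroup]]:
    """n_sets group tables with each group's LWP replaced by k draws
    with replacement from its originals; NDVI untouched.

    Set j uses substream j of the study seed, so individual sets are
    reproducible independently of how many are drawn.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (a single draw carries no SEM)")
    for g in groups:
        if len(g.lwp_reps) < 2:
            raise ValueError(
                f"group {g.key} has fewer than 2 original LWP replicates")
    streams = np.random.SeedSequence(seed).spawn(n_sets)
    tables: list[list[ObservationGroup]] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        table = []
        for g in groups:
            reps = rng.choice(np.asarray(g.lwp_reps, dtype=float), size=k,
                              replace=True)
            gg = copy.copy(g)
            gg.lwp_reps = [float(v) for v in reps]
            table.append(gg)
        tables.append(table)
    return tables


def refit_resamples(tables: list[list[ObservationGroup]], method: str,
                    label: str = "", eval_at: str = "adjusted",
                    fallback_dy: np.ndarray | None = None,
                    ) -> list[FitResult | None]:
    """Fit each resampled table by the named method ("OLS" | "WLS").

    A set that violates a fit precondition is recorded as None (logged),
    not fatal; downstream summaries skip it.  With-replacement draws can
    collide, collapsing a group's resampled SEM to zero; the measurement
    uncertainty of LWP does not actually vanish in that case, so when
    ``fallback_dy`` (the full-replicate group SEMs, in dataset point order)
    is given, zero resampled SEMs are replaced by it (logged per set).
    Without a fallback such points go through the WLS uncertainty floor.
    """
    if method not in ("OLS", "WLS"):
        raise ValueError("method must be 'OLS' or 'WLS'")
    results: list[FitResult | None] = []
    n_failed = 0
    for j, table in enumerate(tables):
        try:
            data = build_regression_dataset(table, label=f"{label}#set{j}")
            if fallback_dy is not None:
                collapsed = data.dy == 0
                if collapsed.any():
                    logger.info(
                        "set %d: %d zero resampled SEM(s) replaced by the "
                        "full-replicate SEM", j, int(collapsed.sum()))
                    data.dy = np.where(collapsed, fallback_dy, data.dy)
            fit = fit_ols(data) if method == "OLS" else fit_wls(data, eval_at)
        except (ValueError, RuntimeError) as exc:
            logger.warning("resample set %d failed %s fit: %s", j, method, exc)
            results.append(None)
            n_failed += 1
            continue
        results.append(fit)
    if n_failed:
        logger.warning("%d of %d resample sets excluded from t-tests",
                       n_failed, len(tables))
    return results


@dataclass
class ResampleStudy:
    """Results of one replicate-count resampling experiment."""

    k: int
    n_sets: int
    seed: int
    reference: dict[str, FitResult]
    per_set: dict[str, list[FitResult | None]]
    t_tests: dict[str, dict[str, TTestResult]] = field(default_factory=dict)

    def coefficient_table(self, method: str) -> np.ndarray:
        """(n_ok, 4) array of (m, c, dm, dc) over successful sets."""
        rows = [(f.m, f.c, f.dm, f.dc) for f in self.per_set[method]
                if f is not None]
        return np.asarray(rows, dtype=float)

    def mean_uncertainties(self, method: str) -> tuple[float, float]:
        tab = self.coefficient_table(method)
        return float(tab[:, 2].mean()), float(tab[:, 3].mean())

    def mean_prediction_error(self, method: str) -> float:
        """Mean over sets of the propagated relative prediction error."""
        vals = [f.rel_pred_error for f in self.per_set[method]
                if f is not None and f.rel_pred_error is not None]
        return float(np.mean(vals))


def run_resample_study(groups: list[ObservationGroup], k: int = 2,
                       n_sets: int = 20, methods=("OLS", "WLS"),
                       seed: int = 0, label: str = "",
                       eval_at: str = "adjusted") -> ResampleStudy:
    """Full experiment: reference fits, n_sets resample refits, t-tests.

    The t-test for each quantity compares the per-set values (e.g. the 20
    dm values) against the single full-replicate value as mu0.
    """
    full = build_regression_dataset(groups, label=label)
    reference = {}
    for method in methods:
        reference[method] = (fit_ols(full) if method == "OLS"
                             else fit_wls(full, eval_at))
    tables = draw_resamples(groups, k=k, n_sets=n_sets, seed=seed)
    per_set = {m: refit_resamples(tables, m, label=label, eval_at=eval_at,
                                  fallback_dy=full.dy)
               for m in methods}
    study = ResampleStudy(k=k, n_sets=n_sets, seed=seed,
                          reference=reference, per_set=per_set)
    for method in methods:
        tab = study.coefficient_table(method)
        ref = reference[method]
        tests = {}
        for col, name in enumerate(QUANTITIES):
            mu0 = getattr(ref, name)
            try:
                tests[name] = one_sample_ttest(tab[:, col], mu0)
            except ValueError as exc:
                logger.warning("t-test for %s/%s skipped: %s",
                               method, name, exc)
        study.t_tests[method] = tests
    return study
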