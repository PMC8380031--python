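"""Synthetic field-campaign generator with known ground truth.

Emulates a one-day diurnal NDVI/LWP calibration campaign: leaf water
potential follows a smooth midday depression (most negative around solar
noon), the per-treatment true NDVI is linearly linked to LWP with a known
slope and intercept, pressure-chamber replicates and plot-level NDVI
replicates carry iid Gaussian noise, and everything is reproducible from a
single seed.  Because the truth (m_true, c_true, noise scales) is known,
parameter recovery and uncertainty calibration of the downstream fitters
are directly measurable.

Defaults emulate the cotton campaign conditions this pipeline was built
around: slope 4.24 MPa per NDVI unit, intercept -5.19 MPa, nine hourly
cells, two irrigation treatments (deficit/full) differing by a small NDVI
offset, 4 LWP replicates and 3 NDVI plot replicates per cell, and noise
scales that put replicate SEMs in the mid single-digit percent of the
measurement ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ObservationGroup, LOCAL_UTC_OFFSET_HOURS


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and sampling design of one simulated campaign.

    Units: slopes in MPa per NDVI unit, intercepts and LWP in MPa, NDVI
    offsets and noise in NDVI units, hours on the local clock.
    ``treatments`` maps treatment label -> additive NDVI offset, so the
    LWP-NDVI slope is shared across treatments while intercepts differ
    (deficit irrigation sits at lower NDVI than full irrigation).

    ``sigma_lof`` is group-level lack-of-fit scatter (MPa): the true LWP of
    a cell deviates from the linear relation by this much, independently of
    replicate measurement noise.  Field calibrations show residual scatter
    well above the replicate SEM -- biology is not exactly a line -- and
    this term is what makes OLS uncertainties insensitive to the LWP
    replicate count while SEM-weighted WLS uncertainties react to it.
    """

    m_true: float = 4.24
    c_true: float = -5.19
    hours: tuple[int, ...] = tuple(range(8, 17))
    treatments: dict[str, float] = field(
        default_factory=lambda: {"D": -0.03, "F": 0.03})
    lwp_base: float = -1.3
    lwp_depth: float = 1.3
    n_lwp_reps: int = 4
    n_ndvi_reps: int = 3
    sigma_lwp: float = 0.12
    sigma_ndvi: float = 0.028
    sigma_lof: float = 0.22
    dawn: float = 6.0
    solar_noon: float = 13.0
    crop: str = "cotton"
    date: str = "2018-08-09"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lwp_reps < 2:
            raise ValueError("n_lwp_reps must be >= 2 (SEM needs replication)")
        if self.n_ndvi_reps < 1:
            raise ValueError("n_ndvi_reps must be >= 1")
        if self.sigma_lwp < 0 or self.sigma_ndvi < 0 or self.sigma_lof < 0:
            raise ValueError("noise scales must be non-negative")
        if self.lwp_depth < 0:
            raise ValueError("lwp_depth must be non-negative")
        if self.m_true == 0:
            raise ValueError("m_true = 0: LWP-NDVI relation not invertible")
        if not self.hours:
            raise ValueError("at least one measurement hour required")

    @property
    def dusk(self) -> float:
        """Daylight window end, symmetric about solar noon."""
        return 2 * self.solar_noon - self.dawn


@dataclass
class SimulatedStudy:
    """Generated observation groups plus the truth that produced them."""

    groups: list[ObservationGroup]
    truth: tuple[float, float]
    config: SimulationConfig


def simulate_diurnal_lwp(config: SimulationConfig, hour: float) -> float:
    """Group-level true LWP at a local clock hour.

    A sine-squared bump over the daylight window models the midday
    depression: s(dawn) = 0, s(solar noon) = 1, returning
    lwp_base - lwp_depth * s(hour).  Deterministic; hours outside the
    daylight window are rejected.
    """
    if not (config.dawn <= hour <= config.dusk):
        raise ValueError(
            f"hour {hour} outside daylight window "
            f"[{config.dawn}, {config.dusk}]")
    s = math.sin(math.pi * (hour - config.dawn) / (config.dusk - config.dawn)) ** 2
    return config.lwp_base - config.lwp_depth * s


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one full campaign: replicated LWP and NDVI per (hour, treatment).

    For each cell the on-line LWP comes from the diurnal curve and the true
    NDVI inverts the linear relation (plus the treatment offset); the
    cell's true LWP then deviates from the line by a lack-of-fit draw
    (``sigma_lof``), and replicates add iid Gaussian measurement noise.
    All randomness flows from per-group substreams spawned
    deterministically from ``config.seed``, so identical configs reproduce
    bit-identical studies.
    """
    cells = [(h, t) for h in config.hours for t in sorted(config.treatments)]
    streams = np.random.SeedSequence(config.seed).spawn(len(cells))
    groups: list[ObservationGroup] = []
    for (hour, trt), ss in zip(cells, streams):
        rng = np.random.default_rng(ss)
        lwp_line = simulate_diurnal_lwp(config, hour)
        ndvi_true = (lwp_line - config.c_true) / config.m_true + config.treatments[trt]
        lwp_true = lwp_line + rng.normal(0.0, config.sigma_lof)
        if not (-1.0 < ndvi_true < 1.0):
            raise ValueError(
                f"true NDVI {ndvi_true:.3f} outside (-1, 1) at hour {hour} "
                f"{trt}; check m_true/c_true/offsets against the LWP range")
        lwp_reps = lwp_true + rng.normal(0.0, config.sigma_lwp, config.n_lwp_reps)
        # NDVI is physically bounded: replicate noise is truncated at the
        # (-1, 1) boundary by redrawing the rare out-of-range tail draws.
        ndvi_reps = ndvi_true + rng.normal(0.0, config.sigma_ndvi, config.n_ndvi_reps)
        for _ in range(100):
            bad = np.abs(ndvi_reps) >= 1
            if not bad.any():
                break
            ndvi_reps[bad] = ndvi_true + rng.normal(0.0, config.sigma_ndvi,
                                                    int(bad.sum()))
        else:
            raise ValueError(
                f"cannot keep NDVI replicates inside (-1, 1) at hour {hour} "
                f"{trt}; sigma_ndvi too large for the true NDVI level")
        groups.append(ObservationGroup(
            crop=config.crop, date=config.date, treatment=trt,
            hour_local=int(hour),
            lwp_reps=[float(v) for v in lwp_reps],
            ndvi_reps=[float(v) for v in ndvi_reps]))
    return SimulatedStudy(groups=groups, truth=(config.m_true, config.c_true),
                          config=config)


# ---------------------------------------------------------------------------
# CSV emitters matching the ingest layouts
# ---------------------------------------------------------------------------

def write_lwp_table(study: SimulatedStudy, path) -> None:
    """LWP replicate CSV: crop, date, treatment, hour, rep, lwp_mpa."""
    rows = []
    for g in study.groups:
        for j, v in enumerate(g.lwp_reps, start=1):
            rows.append((g.crop, g.date, g.treatment, g.hour_local, j, v))
    pd.DataFrame(rows, columns=["crop", "date", "treatment", "hour", "rep",
                                "lwp_mpa"]).to_csv(path, index=False)


def write_scan_log(study: SimulatedStudy, path,
                   records_per_plot: int = 6,
                   idle_records_per_plot: int = 4,
                   base_lat: float = 29.21, base_lon: float = -99.75) -> None:
    """Raw scan-log CSV whose clean aggregation reproduces the study.

    Each NDVI replicate becomes one plot pass of ``records_per_plot`` moving
    readings (2 m spacing, 2 s cadence) with constant reflectance encoding
    exactly that replicate's NDVI (band sum held at 0.8), followed -- after
    a one-minute rest gap, as when the logger keeps running between passes
    -- by ``idle_records_per_plot`` stationary readings at the row end that
    the movement filter is expected to delete.  Timestamps are written in
    UTC (local + 5 h); plot labels are "<treatment>-<k>".
    """
    rows = []
    date = datetime.fromisoformat(study.config.date)
    lat_step = 2.0 / 111_320.0  # ~2 m of latitude per moving record
    for g in study.groups:
        for k, ndvi in enumerate(g.ndvi_reps, start=1):
            rho780 = 0.4 * (1.0 + ndvi)
            rho670 = 0.4 * (1.0 - ndvi)
            t0_local = date + timedelta(hours=g.hour_local,
                                        minutes=5 * k,
                                        seconds=0 if g.treatment == "D" else 150)
            lat0 = base_lat + 0.001 * k
            lon0 = base_lon + (0.0 if g.treatment == "D" else 0.005)
            plot = f"{g.treatment}-{k}"
            for i in range(records_per_plot):
                t_utc = t0_local + timedelta(seconds=2 * i,
                                             hours=-LOCAL_UTC_OFFSET_HOURS)
                rows.append((t_utc.isoformat(), lat0 + lat_step * i, lon0,
                             rho670, 0.3, rho780, plot))
            lat_end = lat0 + lat_step * (records_per_plot - 1)
            for i in range(idle_records_per_plot):
                t_utc = t0_local + timedelta(
                    seconds=2 * records_per_plot + 60 + 2 * i,
                    hours=-LOCAL_UTC_OFFSET_HOURS)
                rows.append((t_utc.isoformat(), lat_end, lon0,
                             rho670, 0.3, rho780, plot))
    df = pd.DataFrame(rows, columns=["timestamp_utc", "lat", "lon",
                                     "rho670", "rho730", "rho780", "plot"])
    df.sort_values("timestamp_utc", kind="stable").to_csv(path, index=False)


def write_truth_sidecar(study: SimulatedStudy, path) -> None:
    """Ground-truth JSON sidecar (m_true, c_true, seed, full config echo)."""
    payload = {"m_true": study.truth[0], "c_true": study.truth[1],
               "seed": study.config.seed, "config": asdict(study.config)}
    Path(path).write_text(json.dumps(payload, indent=2))
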