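"""Ingest raw sensing-cart scan logs and pressure-chamber tables.

The raw material of an NDVI/LWP calibration campaign is (a) a scan log: a
time-stamped stream of three-band canopy reflectance readings (670 nm red,
730 nm red edge, 780 nm NIR) with GPS coordinates, recorded continuously
while a sensing cart is pushed through field plots; and (b) a leaf water
potential (LWP) table: per (crop, date, hour, treatment) groups of 4-6
pressure-chamber readings in MPa.

This module turns both into per-group means and standard errors and pairs
them into a :class:`RegressionDataset`, the input contract of the two
fitters in :mod:`lwpcal.ols` and :mod:`lwpcal.wls`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lwpcal")

#: Fixed UTC -> local offset in hours.  The campaign logger records UTC and
#: local (Central Standard) clock time is obtained as CST = UTC - 5; the
#: constant deliberately bakes in the daylight-saving state of the campaign.
LOCAL_UTC_OFFSET_HOURS = -5

#: metres per degree of latitude (small-area equirectangular approximation)
_M_PER_DEG_LAT = 111_320.0

SCAN_COLUMNS = ["timestamp_utc", "lat", "lon", "rho670", "rho730", "rho780"]
LWP_COLUMNS = ["crop", "date", "treatment", "hour", "rep", "lwp_mpa"]
DATASET_COLUMNS = ["NDVI_mean", "LWP_mean", "NDVI_sem", "LWP_sem"]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_ndvi(rho670, rho780):
    """Normalized difference vegetation index from red and NIR reflectance.

    NDVI = (rho_780 - rho_670) / (rho_780 + rho_670), dimensionless in
    (-1, 1].  Accepts scalars or arrays; both reflectances must be
    non-negative and cannot both be zero.
    """
    r670 = np.asarray(rho670, dtype=float)
    r780 = np.asarray(rho780, dtype=float)
    if np.any(r670 < 0) or np.any(r780 < 0):
        raise ValueError("reflectance must be non-negative")
    total = r670 + r780
    if np.any(total == 0):
        raise ValueError("rho670 + rho780 must be positive to form NDVI")
    out = (r780 - r670) / total
    return float(out) if out.ndim == 0 else out


def utc_to_local(t: datetime) -> datetime:
    """Convert a UTC timestamp to local (CST) clock time: local = UTC - 5 h.

    Naive datetimes are taken as UTC; aware ones are converted to UTC first.
    Returns a naive local-clock datetime.
    """
    if t.tzinfo is not None:
        t = t.astimezone(timezone.utc).replace(tzinfo=None)
    return t + timedelta(hours=LOCAL_UTC_OFFSET_HOURS)


def summarize_group(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and standard error of the mean of one replicate group.

    SEM is the sample standard deviation (n-1 denominator) divided by
    sqrt(n).  With a single value the mean is returned and the SEM is None
    (flagged missing) -- an unreplicated group cannot carry an uncertainty.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ObservationGroup:
    """One (crop, date, hour, treatment) cell before aggregation.

    ``lwp_reps`` holds the individual pressure-chamber readings (MPa,
    conventionally <= 0) and ``ndvi_reps`` the per-plot mean NDVI values
    (one per plot replicate; a single entry for unreplicated campaigns).
    """

    crop: str
    date: str
    treatment: str
    hour_local: int
    lwp_reps: list[float]
    ndvi_reps: list[float]

    def __post_init__(self) -> None:
        if len(self.ndvi_reps) < 1:
            raise ValueError("group needs at least one NDVI replicate")
        if len(self.lwp_reps) < 1:
            raise ValueError("group needs at least one LWP replicate")
        if any(v > 0 for v in self.lwp_reps):
            logger.warning(
                "group %s %s h%02d has positive LWP values; water potential "
                "is conventionally <= 0 MPa", self.date, self.treatment,
                self.hour_local)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.date, self.treatment, self.hour_local)

    def lwp_summary(self) -> tuple[float, float | None]:
        return summarize_group(self.lwp_reps)

    def ndvi_summary(self) -> tuple[float, float | None]:
        return summarize_group(self.ndvi_reps)


@dataclass
class RegressionDataset:
    """Paired (NDVI mean, LWP mean) points with per-point uncertainties.

    ``x``/``dx`` are NDVI means and SEMs, ``y``/``dy`` LWP means and SEMs in
    MPa.  Missing SEMs are stored as NaN; a dataset with any missing SEM is
    ``ols_only`` -- the errors-in-both-coordinates fitter refuses it unless
    the caller supplies a substitute uncertainty policy upstream.
    """

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        n = self.x.size
        if not (self.y.size == self.dx.size == self.dy.size == n):
            raise ValueError("x, y, dx, dy must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(self.dx < 0) or np.any(self.dy < 0):
                raise ValueError("uncertainties must be non-negative")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def ols_only(self) -> bool:
        return bool(np.isnan(self.dx).any() or np.isnan(self.dy).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "NDVI_mean": self.x, "LWP_mean": self.y,
            "NDVI_sem": self.dx, "LWP_sem": self.dy,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "RegressionDataset":
        cols = list(df.columns[:4])
        return cls(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float),
                   df[cols[2]].to_numpy(float), df[cols[3]].to_numpy(float),
                   label=label)

    @classmethod
    def read_csv(cls, path, label: str = "") -> "RegressionDataset":
        """Read the four-column aggregated layout.

        The first four data columns must be, in order: NDVI mean, LWP mean,
        NDVI SEM, LWP SEM.  Extra label columns to the right are ignored.
        """
        return cls.from_frame(pd.read_csv(path), label=label)


# ---------------------------------------------------------------------------
# scan-log filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterPolicy:
    """Declarative cleaning rules for a raw scan log.

    movement_threshold_m / movement_window_s
        A record is idle (sensor parked between scan passes) when every
        other record inside the centred time window lies closer than the
        threshold.  Records whose window holds no neighbour are kept, which
        makes the filter idempotent on already-thinned logs.
    warmup_windows
        Half-open local-time intervals ``(start, end)`` to exclude, e.g. an
        early-morning hour when the sensor had not thermally stabilised.
    time_windows
        If given, keep only records whose local time falls in one of these
        half-open intervals.
    geofences
        Optional ``{plot_label: (lat_min, lat_max, lon_min, lon_max)}``
        bounding boxes; records outside every box are dropped and surviving
        records get/overwrite their ``plot`` label.
    """

    movement_threshold_m: float = 0.5
    movement_window_s: float = 10.0
    warmup_windows: list[tuple[datetime, datetime]] = field(default_factory=list)
    time_windows: list[tuple[datetime, datetime]] | None = None
    geofences: dict[str, tuple[float, float, float, float]] | None = None
    movement_filter: bool = True


def _displacements_ok(lat: np.ndarray, lon: np.ndarray, t_s: np.ndarray,
                      policy: FilterPolicy) -> np.ndarray:
    """Boolean mask of records that are NOT idle under the movement rule."""
    n = lat.size
    keep = np.ones(n, dtype=bool)
    lat0 = math.radians(np.mean(lat)) if n else 0.0
    mx = lon * _M_PER_DEG_LAT * math.cos(lat0)
    my = lat * _M_PER_DEG_LAT
    half = policy.movement_window_s / 2.0
    lo = 0
    hi = 0
    for i in range(n):
        while t_s[lo] < t_s[i] - half:
            lo += 1
        while hi < n and t_s[hi] <= t_s[i] + half:
            hi += 1
        sl = slice(lo, hi)
        if hi - lo < 2:
            continue  # no neighbour to judge movement by
        d = np.hypot(mx[sl] - mx[i], my[sl] - my[i])
        if d.max() < policy.movement_threshold_m:
            keep[i] = False
    return keep


def filter_scan_records(df: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Remove idle, warm-up and out-of-fence records from a scan log.

    ``df`` must carry the scan-log columns and be sorted by time.  Returns
    the surviving subset in the original order; logs counts removed by each
    rule.  An empty result is legal (warned about, not fatal).
    """
    if df.empty:
        return df.copy()
    ts = pd.to_datetime(df["timestamp_utc"])
    if not ts.is_monotonic_increasing:
        raise ValueError("scan log must be sorted by timestamp_utc")
    out = df.copy()
    out["_local"] = ts.map(utc_to_local)
    n0 = len(out)

    if policy.movement_filter:
        t_s = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
        keep = _displacements_ok(out["lat"].to_numpy(float),
                                 out["lon"].to_numpy(float), t_s, policy)
        out = out.loc[keep]
        logger.info("movement filter: %d -> %d records", n0, len(out))

    for start, end in policy.warmup_windows:
        before = len(out)
        mask = (out["_local"] >= start) & (out["_local"] < end)
        out = out.loc[~mask]
        logger.info("warm-up window %s--%s: removed %d records",
                    start, end, before - len(out))

    if policy.time_windows is not None:
        inside = np.zeros(len(out), dtype=bool)
        for start, end in policy.time_windows:
            inside |= ((out["_local"] >= start) & (out["_local"] < end)).to_numpy()
        out = out.loc[inside]

    if policy.geofences is not None:
        labels = np.full(len(out), None, dtype=object)
        lat = out["lat"].to_numpy(float)
        lon = out["lon"].to_numpy(float)
        for name, (la0, la1, lo0, lo1) in policy.geofences.items():
            hit = (lat >= la0) & (lat <= la1) & (lon >= lo0) & (lon <= lo1)
            labels[hit] = name
        out = out.loc[labels != None]  # noqa: E711 -- elementwise object compare
        out = out.assign(plot=labels[labels != None])

    if out.empty:
        logger.warning("all %d scan records were filtered out", n0)
    return out.drop(columns="_local")


# ---------------------------------------------------------------------------
# aggregation and pairing
# ---------------------------------------------------------------------------

def read_scan_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp_utc"])
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan log missing columns: {missing}")
    return df


def read_lwp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LWP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LWP table missing columns: {missing}")
    return df


def aggregate_scans(df: pd.DataFrame,
                    plot_to_treatment: Callable[[str], str] | None = None,
                    ) -> pd.DataFrame:
    """Per (date, hour, treatment, plot) mean NDVI from a cleaned scan log.

    Each plot's hourly mean is one NDVI replicate; the treatment label is
    derived from the plot label (default: text before the first "-").
    """
    if "plot" not in df.columns:
        raise ValueError("aggregation requires a 'plot' column "
                         "(from the log or from geofencing)")
    if plot_to_treatment is None:
        plot_to_treatment = lambda p: str(p).split("-")[0]  # noqa: E731
    work = df.copy()
    local = pd.to_datetime(work["timestamp_utc"]).map(utc_to_local)
    work["date"] = local.map(lambda t: t.date().isoformat())
    work["hour"] = local.map(lambda t: t.hour)
    work["ndvi"] = compute_ndvi(work["rho670"].to_numpy(float),
                                work["rho780"].to_numpy(float))
    work["treatment"] = work["plot"].map(plot_to_treatment)
    grouped = (work.groupby(["date", "hour", "treatment", "plot"],
                            as_index=False)["ndvi"].mean())
    return grouped


def build_observation_groups(scan_summary: pd.DataFrame,
                             lwp_df: pd.DataFrame,
                             crop: str | None = None) -> list[ObservationGroup]:
    """Pair hourly NDVI plot means with LWP replicate groups.

    Cells present on only one side are dropped with a warning -- an hour
    scanned without pressure-chamber sampling (or vice versa) cannot enter
    the calibration.
    """
    ndvi_cells: dict[tuple[str, str, int], list[float]] = {}
    for (date, hour, trt), sub in scan_summary.groupby(["date", "hour", "treatment"]):
        ndvi_cells[(str(date), str(trt), int(hour))] = list(sub["ndvi"])

    groups: list[ObservationGroup] = []
    for (date, trt, hour), sub in lwp_df.groupby(["date", "treatment", "hour"]):
        key = (str(date), str(trt), int(hour))
        if key not in ndvi_cells:
            logger.warning("LWP group %s has no matching NDVI scans; dropped", key)
            continue
        groups.append(ObservationGroup(
            crop=crop or str(sub["crop"].iloc[0]),
            date=key[0], treatment=key[1], hour_local=key[2],
            lwp_reps=list(sub["lwp_mpa"].astype(float)),
            ndvi_reps=ndvi_cells[key],
        ))
    matched = {g.key for g in groups}
    for key in ndvi_cells:
        if key not in matched:
            logger.warning("NDVI cell %s has no matching LWP group; dropped", key)
    return sorted(groups, key=lambda g: g.key)


def build_regression_dataset(groups: Iterable[ObservationGroup],
                             label: str = "",
                             dx_policy: float | None = None,
                             ) -> RegressionDataset:
    """One regression point per observation group, ordered by (date,
    treatment, hour).

    x = NDVI mean, y = LWP mean, dx = NDVI SEM, dy = LWP SEM.  Unreplicated
    NDVI (single scan pass, as in a non-replicated wheat campaign) yields a
    missing dx: the point is still emitted, with dx = NaN, and the dataset
    becomes OLS-only unless ``dx_policy`` supplies a substitute NDVI
    uncertainty.  Pooling treatments is the caller's decision -- simply pass
    the union of both treatments' groups.
    """
    ordered = sorted(groups, key=lambda g: g.key)
    if not ordered:
        raise ValueError("no observation groups to assemble")
    x, y, dx, dy = [], [], [], []
    for g in ordered:
        xm, xs = g.ndvi_summary()
        ym, ys = g.lwp_summary()
        if xs is None and dx_policy is not None:
            xs = float(dx_policy)
        x.append(xm)
        y.append(ym)
        dx.append(np.nan if xs is None else xs)
        dy.append(np.nan if ys is None else ys)
    ds = RegressionDataset(np.array(x), np.array(y), np.array(dx),
                           np.array(dy), label=label)
    if ds.ols_only:
        logger.warning("dataset %r has missing SEMs and is OLS-only", label)
    return ds
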