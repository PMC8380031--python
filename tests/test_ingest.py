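"""Ingest: NDVI computation, time conversion, filtering, aggregation."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lwpcal import (
    FilterPolicy,
    ObservationGroup,
    RegressionDataset,
    build_regression_dataset,
    compute_ndvi,
    filter_scan_records,
    summarize_group,
    utc_to_local,
)


class TestComputeNdvi:
    @pytest.mark.parametrize("r670, r780, expected", [
        (0.3, 0.3, 0.0),
        (0.0, 0.4, 1.0),
        (0.1, 0.5, 0.4 / 0.6),
    ])
    def test_values(self, r670, r780, expected):
        assert compute_ndvi(r670, r780) == pytest.approx(expected, abs=1e-12)

    def test_rejects_zero_sum_and_negative(self):
        with pytest.raises(ValueError):
            compute_ndvi(0.0, 0.0)
        with pytest.raises(ValueError):
            compute_ndvi(-0.1, 0.5)

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_range(self, r670, r780):
        assert -1.0 < compute_ndvi(r670, r780) < 1.0


class TestUtcToLocal:
    @pytest.mark.parametrize("utc, local", [
        (datetime(2018, 8, 9, 18, 30), datetime(2018, 8, 9, 13, 30)),
        (datetime(2018, 8, 9, 5, 0), datetime(2018, 8, 9, 0, 0)),
        (datetime(2018, 8, 9, 3, 0), datetime(2018, 8, 8, 22, 0)),
    ])
    def test_fixed_offset(self, utc, local):
        assert utc_to_local(utc) == local


class TestSummarizeGroup:
    @pytest.mark.parametrize("values, mean, sem", [
        ([-1.2, -1.2, -1.2, -1.2], -1.2, 0.0),
        ([-1.0, -1.2, -1.4, -1.6], -1.3, np.sqrt(0.2 / 3) / 2),
        ([0.0, 1.0], 0.5, 0.5),
    ])
    def test_values(self, values, mean, sem):
        got_mean, got_sem = summarize_group(values)
        assert got_mean == pytest.approx(mean)
        assert got_sem == pytest.approx(sem, abs=1e-12)

    def test_single_value_has_no_sem(self):
        mean, sem = summarize_group([-0.8])
        assert mean == -0.8 and sem is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])

    @given(st.lists(st.floats(-3, 0), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        m1, s1 = summarize_group(values)
        m2, s2 = summarize_group(shuffled)
        assert m1 == pytest.approx(m2, rel=1e-12, abs=1e-12)
        assert s1 == pytest.approx(s2, rel=1e-9, abs=1e-12)


def _scan_frame(rows):
    return pd.DataFrame(rows, columns=["timestamp_utc", "lat", "lon",
                                       "rho670", "rho730", "rho780"])


def _moving_log(n=100, start=datetime(2018, 8, 9, 13, 0), step_m=2.0):
    """n records advancing step_m metres every 2 seconds."""
    rows = []
    for i in range(n):
        rows.append((start + timedelta(seconds=2 * i),
                     29.0 + i * step_m / 111_320.0, -99.0, 0.1, 0.3, 0.5))
    return _scan_frame(rows)


class TestFilterScanRecords:
    def test_empty_input(self):
        out = filter_scan_records(_scan_frame([]), FilterPolicy())
        assert out.empty

    def test_all_stationary_removed(self):
        rows = [(datetime(2018, 8, 9, 13, 0) + timedelta(seconds=2 * i),
                 29.0, -99.0, 0.1, 0.3, 0.5) for i in range(50)]
        out = filter_scan_records(_scan_frame(rows), FilterPolicy())
        assert out.empty

    def test_warmup_window_count(self):
        # 100 records; 30 fall inside a declared warm-up window (movement off)
        df = _moving_log(100)
        local_start = utc_to_local(datetime(2018, 8, 9, 13, 0))
        window = (local_start, local_start + timedelta(seconds=60))  # 30 recs
        policy = FilterPolicy(movement_filter=False, warmup_windows=[window])
        out = filter_scan_records(df, policy)
        assert len(out) == 70

    def test_moving_records_survive(self):
        out = filter_scan_records(_moving_log(40), FilterPolicy())
        assert len(out) == 40

    def test_idempotent(self):
        df = pd.concat([
            _moving_log(20),
            _scan_frame([(datetime(2018, 8, 9, 13, 5) + timedelta(seconds=2 * i),
                          29.001, -99.0, 0.1, 0.3, 0.5) for i in range(10)]),
        ]).sort_values("timestamp_utc").reset_index(drop=True)
        once = filter_scan_records(df, FilterPolicy())
        twice = filter_scan_records(once.reset_index(drop=True), FilterPolicy())
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_unsorted_rejected(self):
        df = _moving_log(5).iloc[::-1]
        with pytest.raises(ValueError):
            filter_scan_records(df, FilterPolicy())


def _group(date, trt, hour, lwp, ndvi, crop="cotton"):
    return ObservationGroup(crop=crop, date=date, treatment=trt,
                            hour_local=hour, lwp_reps=lwp, ndvi_reps=ndvi)


class TestBuildRegressionDataset:
    def test_one_point_per_group(self):
        groups = [_group("2018-08-09", "D", h,
                         [-1.0 - 0.1 * h, -1.2 - 0.1 * h],
                         [0.6, 0.7, 0.65]) for h in range(8, 17)]
        ds = build_regression_dataset(groups)
        assert len(ds) == 9
        assert ds.x[0] == pytest.approx(np.mean([0.6, 0.7, 0.65]))
        assert ds.y[0] == pytest.approx(np.mean([-1.8, -2.0]))

    def test_pooled_treatments(self):
        groups = [_group("2018-08-09", t, h, [-1.0, -1.2], [0.6, 0.7])
                  for t in ("D", "F") for h in range(8, 17)]
        assert len(build_regression_dataset(groups)) == 18

    def test_unreplicated_ndvi_is_ols_only(self):
        groups = [_group("2018-04-12", "F", h, [-1.0, -1.2], [0.55 + 0.01 * h])
                  for h in range(9, 13)]
        ds = build_regression_dataset(groups)
        assert ds.ols_only
        assert np.isnan(ds.dx).all()

    def test_dx_policy_fills_missing(self):
        groups = [_group("2018-04-12", "F", h, [-1.0, -1.2], [0.55 + 0.01 * h])
                  for h in range(9, 13)]
        ds = build_regression_dataset(groups, dx_policy=0.02)
        assert not ds.ols_only
        assert np.all(ds.dx == 0.02)

    def test_deterministic_ordering(self):
        groups = [_group("2018-08-09", "F", 10, [-1.0, -1.1], [0.7]),
                  _group("2018-08-09", "D", 12, [-2.0, -2.1], [0.6]),
                  _group("2018-08-09", "D", 9, [-1.5, -1.6], [0.65])]
        ds = build_regression_dataset(groups)
        # sorted by (date, treatment, hour): D9, D12, F10
        assert ds.x == pytest.approx([0.65, 0.6, 0.7])


class TestRegressionDatasetIO:
    def test_csv_roundtrip(self, tmp_path):
        ds = RegressionDataset([0.6, 0.7, 0.8], [-2.0, -1.5, -1.0],
                               [0.01, 0.02, 0.01], [0.05, 0.06, 0.05])
        path = tmp_path / "data.csv"
        ds.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "NDVI_mean,LWP_mean,NDVI_sem,LWP_sem"
        back = RegressionDataset.read_csv(path)
        assert back.x == pytest.approx(ds.x)
        assert back.dy == pytest.approx(ds.dy)

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            RegressionDataset([0.1, 0.2], [1.0, 2.0], [-0.01, 0.01],
                              [0.1, 0.1])
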