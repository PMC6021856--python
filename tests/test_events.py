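"""Event-log I/O, signature-matrix resampling and daily aggregation."""

import io
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homesig.events import (
    SchemaError,
    SensorSpec,
    binarize_signature,
    daily_aggregate,
    read_event_log,
    resample_to_signature,
    write_event_log,
)

from conftest import make_log

CSV_HEADER = "gtw_id,obj_id,variable_id,ts,int_value,float_value,string_value,flags\n"


class TestReadEventLog:
    def test_valid_rows_sorted(self, tmp_path, bed_spec):
        p = tmp_path / "events.csv"
        p.write_text(
            CSV_HEADER
            + "gw,bed,status,2018-06-01T10:02:00Z,0,,,\n"
            + "gw,bed,status,2018-06-01T10:00:00Z,1,,,\n"
            + "gw,bed,keepalive,2018-06-01T10:01:00Z,1,,,\n"
        )
        log = read_event_log(p, [bed_spec])
        assert len(log) == 3 and not log.errors
        assert log.frame["ts"].is_monotonic_increasing

    def test_both_value_fields_is_row_error(self, tmp_path, bed_spec):
        p = tmp_path / "events.csv"
        p.write_text(CSV_HEADER + "gw,bed,status,2018-06-01T10:00:00Z,1,3.5,,\n")
        log = read_event_log(p, [bed_spec])
        assert len(log) == 0
        assert log.errors[0].line == 2
        assert "both" in log.errors[0].message

    def test_unparseable_timestamp_reported_with_line(self, tmp_path, bed_spec):
        p = tmp_path / "events.csv"
        p.write_text(
            CSV_HEADER
            + "gw,bed,status,2018-06-01T10:00:00Z,1,,,\n"
            + "gw,bed,status,not-a-time,0,,,\n"
        )
        log = read_event_log(p, [bed_spec])
        assert len(log) == 1
        assert log.errors[0].line == 3
        assert "timestamp" in log.errors[0].message

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(CSV_HEADER)
        log = read_event_log(p, [])
        assert len(log) == 0 and not log.errors

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("gtw_id,obj_id,ts\ngw,bed,2018-06-01T10:00:00Z\n")
        with pytest.raises(SchemaError):
            read_event_log(p, [])

    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip(self, tmp_path, bed_spec, toilet_spec, fmt):
        log = make_log(
            [
                ("bed", "status", "2018-06-01T10:00:00Z", 1, None),
                ("toilet", "status", "2018-06-01T10:00:30Z", 1, None),
                ("bed", "status", "2018-06-01T10:05:00Z", 0, None),
                ("bed", "battery", "2018-06-01T12:00:00Z", None, 87.5),
            ]
        )
        p = tmp_path / f"events.{fmt}"
        write_event_log(log, p, fmt=fmt)
        back = read_event_log(p, [bed_spec, toilet_spec])
        assert len(back) == len(log) and not back.errors
        pd.testing.assert_series_equal(back.frame["ts"], log.frame["ts"])
        pd.testing.assert_series_equal(back.frame["int_value"], log.frame["int_value"])
        pd.testing.assert_series_equal(back.frame["float_value"], log.frame["float_value"])


class TestResample:
    def test_any_overlap_marks_bins(self, bed_spec):
        # ON 10:00:30, OFF 10:02:30 touches bins 10:00, 10:01, 10:02
        log = make_log(
            [
                ("bed", "status", "2018-06-01T10:00:30Z", 1, None),
                ("bed", "status", "2018-06-01T10:02:30Z", 0, None),
            ]
        )
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:05:00Z")),
        )
        assert sig.data["bed"].tolist() == [1, 1, 1, 0, 0]

    def test_off_at_bin_boundary_excludes_bin(self, bed_spec):
        log = make_log(
            [
                ("bed", "status", "2018-06-01T10:00:00Z", 1, None),
                ("bed", "status", "2018-06-01T10:02:00Z", 0, None),
            ]
        )
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:03:00Z")),
        )
        assert sig.data["bed"].tolist() == [1, 1, 0]

    def test_empty_span_gives_zero_rows(self, bed_spec):
        log = make_log([])
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T00:00:00Z"), pd.Timestamp("2018-06-01T01:00:00Z")),
        )
        assert sig.data.shape == (60, 1)
        assert (sig.data["bed"] == 0).all()

    def test_unclosed_on_held_open_with_warning(self, bed_spec):
        log = make_log([("bed", "status", "2018-06-01T10:00:00Z", 1, None)])
        with pytest.warns(UserWarning, match="held open"):
            sig = resample_to_signature(
                log, [bed_spec],
                span=(pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:05:00Z")),
            )
        assert (sig.data["bed"] == 1).all()

    def test_power_meter_time_weighted_and_binarized(self, tv_spec):
        # 100 W for two full minutes then 0: mean 100 in those bins, above the 50 W threshold
        log = make_log(
            [
                ("tv", "power", "2018-06-01T10:00:00Z", None, 100.0),
                ("tv", "power", "2018-06-01T10:02:00Z", None, 0.0),
            ]
        )
        sig = resample_to_signature(
            log, [tv_spec],
            span=(pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:04:00Z")),
        )
        assert sig.data["tv"].tolist() == [100.0, 100.0, 0.0, 0.0]
        b = binarize_signature(sig, [tv_spec])
        assert b.data["tv"].tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_impulsive_counts_per_bin(self, toilet_spec):
        log = make_log(
            [
                ("toilet", "status", "2018-06-01T10:00:10Z", 1, None),
                ("toilet", "status", "2018-06-01T10:00:50Z", 1, None),
                ("toilet", "status", "2018-06-01T10:02:10Z", 1, None),
            ]
        )
        sig = resample_to_signature(
            log, [toilet_spec],
            span=(pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:03:00Z")),
        )
        assert sig.data["toilet"].tolist() == [2.0, 0.0, 1.0]

    def test_binarization_monotone_in_threshold(self):
        log = make_log(
            [
                ("tv", "power", "2018-06-01T10:00:00Z", None, 60.0),
                ("tv", "power", "2018-06-01T10:01:00Z", None, 30.0),
                ("tv", "power", "2018-06-01T10:02:00Z", None, 0.0),
            ]
        )
        span = (pd.Timestamp("2018-06-01T10:00:00Z"), pd.Timestamp("2018-06-01T10:03:00Z"))
        prev = None
        for thr in (10.0, 40.0, 70.0):
            spec = SensorSpec("tv", "real_valued", binarize_threshold=thr)
            sig = resample_to_signature(log, [spec], span=span)
            cur = binarize_signature(sig, [spec]).data["tv"].to_numpy()
            if prev is not None:
                assert (cur <= prev).all()
            prev = cur


class TestDailyAggregate:
    def _day_log(self, sessions):
        rows = []
        for on, off in sessions:
            rows.append(("bed", "status", on, 1, None))
            rows.append(("bed", "status", off, 0, None))
        return make_log(rows)

    def test_single_session(self, bed_spec):
        log = self._day_log([("2018-06-01T06:00:00Z", "2018-06-01T18:00:00Z")])
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T00:00:00Z"), pd.Timestamp("2018-06-02T00:00:00Z")),
        )
        (agg,) = daily_aggregate(sig, log, [bed_spec])
        assert agg.active_hours == pytest.approx(12.0)
        assert agg.event_count == 1 and not agg.partial

    def test_two_sessions(self, bed_spec):
        log = self._day_log(
            [
                ("2018-06-01T06:00:00Z", "2018-06-01T07:00:00Z"),
                ("2018-06-01T20:00:00Z", "2018-06-01T21:00:00Z"),
            ]
        )
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T00:00:00Z"), pd.Timestamp("2018-06-02T00:00:00Z")),
        )
        (agg,) = daily_aggregate(sig, log, [bed_spec])
        assert agg.active_hours == pytest.approx(2.0)
        assert agg.event_count == 2

    def test_partial_day_flagged(self, bed_spec):
        log = self._day_log([("2018-06-01T06:00:00Z", "2018-06-01T07:00:00Z")])
        sig = resample_to_signature(
            log, [bed_spec],
            span=(pd.Timestamp("2018-06-01T00:00:00Z"), pd.Timestamp("2018-06-01T12:00:00Z")),
        )
        (agg,) = daily_aggregate(sig, log, [bed_spec])
        assert agg.partial

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=2000),
                st.integers(min_value=1, max_value=600),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_conservation_of_active_time(self, raw_sessions):
        """Summed daily active hours match exact ON time within one bin per session."""
        base = pd.Timestamp("2018-06-01T00:00:00Z")
        sessions, cursor = [], 0
        for gap, dur in raw_sessions:  # build non-overlapping sessions
            on = cursor + gap
            off = on + dur
            sessions.append((base + timedelta(minutes=on), base + timedelta(minutes=off)))
            cursor = off + 1
        n_days = int(np.ceil((sessions[-1][1] - base) / timedelta(days=1))) or 1
        log = self._day_log([(s.isoformat(), e.isoformat()) for s, e in sessions])
        spec = SensorSpec("bed", "binary_state")
        sig = resample_to_signature(
            log, [spec], span=(base, base + timedelta(days=n_days))
        )
        aggs = daily_aggregate(sig, log, [spec])
        total = sum(a.active_hours for a in aggs)
        exact = sum((e - s) / timedelta(hours=1) for s, e in sessions)
        assert abs(total - exact) <= len(sessions) * (2.0 / 60.0)
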