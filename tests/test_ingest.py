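import io
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ambientropy as amb
from ambientropy.entropy import EntropySeries
from ambientropy.ingest import (
    EXCLUDED_LOW_ACTIVITY,
    EXCLUDED_VACATION,
    KEPT,
    EmptyInputError,
    MalformedRowError,
)


def _csv(rows):
    return io.StringIO("timestamp,sensor_id,event_type\n" + "\n".join(rows))


class TestReadEvents:
    def test_parses_and_flags_usable(self):
        ev = amb.read_events(
            _csv(
                [
                    "2018-06-05T08:00:00,A,ON",
                    "2018-06-05T08:01:00,B,OFF",
                    "2018-06-05T08:02:00,A,ON",
                ]
            )
        )
        assert len(ev) == 3
        assert ev["usable"].sum() == 2

    def test_out_of_order_rows_sorted_stably(self):
        ev = amb.read_events(
            _csv(
                [
                    "2018-06-05T09:00:00,B,ON",
                    "2018-06-05T08:00:00,A,ON",
                    "2018-06-05T09:00:00,C,ON",  # tie with first row: file order kept
                ]
            )
        )
        assert ev["sensor_id"].tolist() == ["A", "B", "C"]

    def test_blank_sensor_id_names_line(self):
        with pytest.raises(MalformedRowError, match="line 3"):
            amb.read_events(
                _csv(["2018-06-05T08:00:00,A,ON", "2018-06-05T08:01:00, ,ON"])
            )

    def test_bad_timestamp_names_line(self):
        with pytest.raises(MalformedRowError, match="line 2"):
            amb.read_events(_csv(["not-a-time,A,ON"]))

    def test_empty_file_raises(self):
        with pytest.raises(EmptyInputError):
            amb.read_events(_csv([]))


class TestDailyTrajectories:
    def test_collapse_repeats_on(self):
        ev = amb.read_events(
            _csv(
                [
                    f"2018-06-05T08:0{i}:00,{s},ON"
                    for i, s in enumerate(["A", "A", "B", "A"])
                ]
            )
        )
        (traj,) = amb.build_daily_trajectories(ev, collapse_repeats=True)
        assert traj.symbols == ("A", "B", "A")
        assert (traj.n, traj.N, traj.raw_n) == (3, 2, 4)

    def test_collapse_repeats_off(self):
        ev = amb.read_events(
            _csv(
                [
                    f"2018-06-05T08:0{i}:00,{s},ON"
                    for i, s in enumerate(["A", "A", "B", "A"])
                ]
            )
        )
        (traj,) = amb.build_daily_trajectories(ev, collapse_repeats=False)
        assert traj.symbols == ("A", "A", "B", "A")
        assert (traj.n, traj.N) == (4, 2)

    def test_events_partitioned_at_midnight(self):
        ev = amb.read_events(
            _csv(["2018-06-05T23:59:00,A,ON", "2018-06-06T00:01:00,B,ON"])
        )
        trajs = amb.build_daily_trajectories(ev)
        assert [t.date for t in trajs] == [date(2018, 6, 5), date(2018, 6, 6)]

    @given(
        syms=st.lists(st.sampled_from("ABCD"), min_size=1, max_size=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_no_adjacent_repeats_after_collapse(self, syms):
        rows = [f"2018-06-05T{8 + i // 60:02d}:{i % 60:02d}:00,{s},ON" for i, s in enumerate(syms)]
        ev = amb.read_events(_csv(rows))
        (traj,) = amb.build_daily_trajectories(ev, collapse_repeats=True)
        assert all(a != b for a, b in zip(traj.symbols, traj.symbols[1:]))
        # order preservation: collapsed sequence is the original minus repeats
        collapsed = [s for i, s in enumerate(syms) if i == 0 or s != syms[i - 1]]
        assert list(traj.symbols) == collapsed


def _traj(day, n_on):
    return amb.DailyTrajectory(
        date=day, symbols=("A",) * 1, n=1, N=1, raw_n=n_on
    )


class TestFilterDays:
    def test_threshold_and_vacation_precedence(self):
        trajs = [
            _traj(date(2018, 6, 5), 11),
            _traj(date(2018, 6, 6), 12),
            _traj(date(2018, 6, 7), 300),
        ]
        kept, report = amb.filter_days(trajs, vacation_dates=[date(2018, 6, 7)])
        statuses = {r.date: r.status for r in report}
        assert statuses[date(2018, 6, 5)] == EXCLUDED_LOW_ACTIVITY  # 11 < 12
        assert statuses[date(2018, 6, 6)] == KEPT  # boundary inclusive
        assert statuses[date(2018, 6, 7)] == EXCLUDED_VACATION  # metadata wins
        assert [t.date for t in kept] == [date(2018, 6, 6)]

    def test_report_partitions_days(self):
        trajs = [_traj(date(2018, 6, d), 5 + d) for d in range(1, 20)]
        kept, report = amb.filter_days(trajs)
        assert len(report) == len(trajs)
        n_kept = sum(r.status == KEPT for r in report)
        assert n_kept == len(kept)
        assert len({r.date for r in report}) == len(trajs)


class TestIsolatedOutliers:
    def _series(self, pairs):
        return EntropySeries(
            dates=tuple(d for d, _ in pairs),
            values=np.array([v for _, v in pairs]),
        )

    def test_isolated_spike_removed(self):
        days = [date(2018, 6, 1) + timedelta(days=i) for i in range(31)]
        vals = [1.5 + 0.01 * (i % 3) for i in range(31)]
        vals[15] = 9.0
        series = self._series(list(zip(days, vals)))
        filtered, rule, removed = amb.remove_isolated_outliers(series)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert rule.upper == pytest.approx(q3 + 1.5 * (q3 - q1))
        assert 9.0 > rule.upper
        assert removed == [days[15]]
        assert filtered.n == 30

    def test_adjacent_outliers_mutually_protected(self):
        days = [date(2018, 6, 1) + timedelta(days=i) for i in range(32)]
        vals = [1.5 + 0.01 * (i % 3) for i in range(32)]
        vals[15] = vals[16] = 9.0  # consecutive dates: each has a +/-3-day peer
        series = self._series(list(zip(days, vals)))
        filtered, _, removed = amb.remove_isolated_outliers(series)
        assert removed == []
        assert filtered.n == 32

    def test_identical_values_nothing_removed(self):
        days = [date(2018, 6, 1) + timedelta(days=i) for i in range(10)]
        series = self._series([(d, 1.5) for d in days])
        filtered, rule, removed = amb.remove_isolated_outliers(series)
        assert rule.iqr == 0 and rule.lower == rule.upper == 1.5
        assert removed == [] and filtered.n == 10

    def test_idempotent_with_frozen_fences(self):
        days = [date(2018, 6, 1) + timedelta(days=i) for i in range(31)]
        vals = [1.5 + 0.02 * (i % 5) for i in range(31)]
        vals[5] = 8.0
        series = self._series(list(zip(days, vals)))
        filtered, rule, removed = amb.remove_isolated_outliers(series)
        assert removed
        # second pass: no survivor lies outside the first-pass fences
        assert all(rule.lower <= v <= rule.upper for v in filtered.values)

    def test_too_short_series_errors(self):
        series = self._series([(date(2018, 6, 1), 1.0), (date(2018, 6, 2), 2.0)])
        with pytest.raises(ValueError):
            amb.remove_isolated_outliers(series)
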