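"""Reading motion-sensor event logs and building daily symbol trajectories.

A PIR motion sensor reports an ON event when movement enters its viewing
area; the chronological sequence of the sensors that fired, one sequence
per calendar day, is the resident's daily movement trajectory. This module
parses raw event CSVs, partitions ON events at local midnight, and applies
the day-level exclusion rules: explicit vacation days, low-activity days
(fewer than 12 ON events, which empirically correspond to vacations and
sensor errors rather than occupancy), and isolated entropy outliers by the
Tukey IQR fence with a +/-3-day isolation window so that genuine multi-day
episodes are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .entropy import EntropySeries

__all__ = [
    "SensorEvent",
    "DailyTrajectory",
    "DayFilterRecord",
    "OutlierRule",
    "IngestConfig",
    "EmptyInputError",
    "MalformedRowError",
    "read_events",
    "build_daily_trajectories",
    "filter_days",
    "remove_isolated_outliers",
    "trajectories_to_frame",
]

KEPT = "kept"
EXCLUDED_VACATION = "excluded_vacation"
EXCLUDED_LOW_ACTIVITY = "excluded_low_activity"
EXCLUDED_OUTLIER = "excluded_outlier"


class EmptyInputError(ValueError):
    """The event log contains no rows."""


class MalformedRowError(ValueError):
    """A row of the event log failed validation; the message names the line."""


@dataclass(frozen=True)
class SensorEvent:
    timestamp: pd.Timestamp
    sensor_id: str
    event_type: str  # "ON", "OFF" or "other"

    @property
    def usable(self) -> bool:
        return self.event_type == "ON"


@dataclass(frozen=True)
class DailyTrajectory:
    """One day's ordered sequence of sensor symbols.

    ``n`` is the (possibly repeat-collapsed) symbol count, ``N`` the number
    of distinct sensors, ``raw_n`` the pre-collapse ON-event count used by
    the low-activity day filter.
    """

    date: _date
    symbols: tuple[str, ...]
    n: int
    N: int
    raw_n: int

    def __post_init__(self) -> None:
        if self.n != len(self.symbols) or self.n < 1:
            raise ValueError("n must equal len(symbols) >= 1")
        if not 1 <= self.N <= self.n:
            raise ValueError("need 1 <= N <= n")


@dataclass(frozen=True)
class DayFilterRecord:
    date: _date
    status: str
    event_count: int


@dataclass(frozen=True)
class OutlierRule:
    """Tukey fences on the daily-entropy distribution, in bits."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    isolation_window_days: int


@dataclass(frozen=True)
class IngestConfig:
    min_events: int = 12
    collapse_repeats: bool = True
    outlier_window_days: int = 3
    timezone: str = "UTC"


def read_events(path, config: IngestConfig | None = None) -> pd.DataFrame:
    """Parse an event-log CSV into a timestamp-sorted event table.

    Columns required: ``timestamp,sensor_id,event_type``. Timestamps are
    ISO-8601; naive ones are localized to ``config.timezone``, aware ones
    converted to it. Non-ON events are retained but marked unusable. Ties
    in timestamps keep input file order (stable sort).
    """
    config = config or IngestConfig()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"timestamp", "sensor_id", "event_type"} - set(raw.columns)
    if missing:
        raise MalformedRowError(f"missing columns: {sorted(missing)}")
    if len(raw) == 0:
        raise EmptyInputError(f"event log {path} contains no rows")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601", utc=False)
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise MalformedRowError(f"line {line}: unparseable timestamp {raw['timestamp'].iloc[line - 2]!r}")
    blank = raw["sensor_id"].str.strip() == ""
    if blank.any():
        line = int(np.flatnonzero(blank.to_numpy())[0]) + 2
        raise MalformedRowError(f"line {line}: blank sensor_id")

    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(config.timezone)
    else:
        ts = ts.dt.tz_convert(config.timezone)

    etype = raw["event_type"].str.strip().str.upper()
    etype = etype.where(etype.isin(["ON", "OFF"]), "other")

    out = pd.DataFrame(
        {
            "timestamp": ts,
            "sensor_id": raw["sensor_id"].str.strip(),
            "event_type": etype,
            "usable": etype == "ON",
        }
    )
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def build_daily_trajectories(
    events: pd.DataFrame, collapse_repeats: bool = True
) -> list[DailyTrajectory]:
    """Partition ON events at local midnight into per-day symbol sequences.

    With ``collapse_repeats`` consecutive firings of the same sensor merge
    into one symbol, so the trajectory records transitions between viewing
    areas rather than dwell-time re-triggers. Days without ON events are
    simply absent.
    """
    on = events.loc[events["usable"]]
    trajectories: list[DailyTrajectory] = []
    for day, grp in on.groupby(on["timestamp"].dt.date, sort=True):
        syms = grp["sensor_id"].tolist()
        raw_n = len(syms)
        if collapse_repeats:
            syms = [s for i, s in enumerate(syms) if i == 0 or s != syms[i - 1]]
        trajectories.append(
            DailyTrajectory(
                date=day,
                symbols=tuple(syms),
                n=len(syms),
                N=len(set(syms)),
                raw_n=raw_n,
            )
        )
    return trajectories


def filter_days(
    trajectories: Sequence[DailyTrajectory],
    vacation_dates: Iterable[_date] = (),
    min_events: int = 12,
) -> tuple[list[DailyTrajectory], list[DayFilterRecord]]:
    """Exclude vacation days and days with fewer than ``min_events`` ON events.

    Explicit vacation metadata takes precedence over the count rule. The
    returned report covers every input day exactly once; the kept/excluded
    statuses partition the days.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    vacation = set(vacation_dates)
    kept: list[DailyTrajectory] = []
    report: list[DayFilterRecord] = []
    for traj in trajectories:
        if traj.date in vacation:
            status = EXCLUDED_VACATION
        elif traj.raw_n < min_events:
            status = EXCLUDED_LOW_ACTIVITY
        else:
            status = KEPT
            kept.append(traj)
        report.append(DayFilterRecord(date=traj.date, status=status, event_count=traj.raw_n))
    return kept, report


def remove_isolated_outliers(
    series: EntropySeries, rule_window: int = 3
) -> tuple[EntropySeries, OutlierRule, list[_date]]:
    """Drop isolated entropy outliers by the Tukey IQR rule.

    A day is an outlier when its entropy lies outside
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` (quartiles by linear interpolation on
    the unfiltered series). Only outliers with **no other outlier within**
    ``rule_window`` calendar days are removed, so that temporary multi-day
    shifts — which are signal for the change-point stage — survive.
    """
    if series.n < 4:
        raise ValueError(f"need >= 4 points to define quartiles, got {series.n}")
    values = series.values
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q3 - q1
    rule = OutlierRule(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower=float(q1 - 1.5 * iqr),
        upper=float(q3 + 1.5 * iqr),
        isolation_window_days=rule_window,
    )
    flagged = [
        d
        for d, v in zip(series.dates, values)
        if v < rule.lower or v > rule.upper
    ]
    window = timedelta(days=rule_window)
    removed = [
        d
        for d in flagged
        if not any(o != d and abs(o - d) <= window for o in flagged)
    ]
    removed_set = set(removed)
    keep = [i for i, d in enumerate(series.dates) if d not in removed_set]
    filtered = EntropySeries(
        dates=tuple(series.dates[i] for i in keep), values=values[keep]
    )
    return filtered, rule, removed


def trajectories_to_frame(trajectories: Sequence[DailyTrajectory]) -> pd.DataFrame:
    """Tabular form used by the CSV interfaces (symbols pipe-delimited)."""
    return pd.DataFrame(
        {
            "date": [t.date for t in trajectories],
            "n": [t.n for t in trajectories],
            "N": [t.N for t in trajectories],
            "raw_n": [t.raw_n for t in trajectories],
            "symbols": ["|".join(t.symbols) for t in trajectories],
        }
    )
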