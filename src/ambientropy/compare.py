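"""Segment categorization against external evidence, and Welch comparisons.

Detected segments are corroborated with dated external records (interview
notes about visitors, maintenance logs, battery telemetry): an annotation
within a +/-2-day window of a segment's start date assigns the segment one
of five categories — single-occupant (1), single-occupant (2, after a
system change such as an added sensor), multiple-occupant, system
malfunction, or unknown when nothing corroborates the change point. The
two single-occupant categories together form the "normal" day set used for
routine analyses (weekday/weekend and similar group contrasts).

Mean daily entropy between categories and day groups is compared with
Welch's t-test (unequal variances, Welch-Satterthwaite degrees of
freedom), two-sided, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .changepoint import Segmentation
from .entropy import EntropySeries

__all__ = [
    "SegmentAnnotation",
    "SegmentCategory",
    "WelchResult",
    "ANNOTATION_KINDS",
    "SINGLE_OCCUPANT_CATEGORIES",
    "categorize_segments",
    "day_categories",
    "welch_t",
    "pairwise_segment_tests",
    "group_comparison",
    "weekday_weekend",
]

ANNOTATION_KINDS = frozenset(
    {
        "visitor_arrive",
        "visitor_leave",
        "sensor_add",
        "sensor_replace",
        "battery_replace",
        "battery_drained",
        "network_problem",
        "other",
    }
)

_MALFUNCTION = {"battery_drained", "network_problem"}
_REVERT = {"visitor_leave", "sensor_replace", "battery_replace"}

SINGLE_OCCUPANT_CATEGORIES = ("single_occupant_1", "single_occupant_2")


@dataclass(frozen=True)
class SegmentAnnotation:
    date: _date
    kind: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")


@dataclass(frozen=True)
class SegmentCategory:
    segment: int  # 1-based
    category: str
    evidence: tuple[SegmentAnnotation, ...] = ()


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def categorize_segments(
    series: EntropySeries,
    segmentation: Segmentation,
    annotations: Iterable[SegmentAnnotation],
    window: int = 2,
    initial_state: str = "single_occupant_1",
) -> list[SegmentCategory]:
    """Assign each segment a five-way category from nearby dated evidence.

    Only annotations dated within ``window`` days of a segment's start date
    count as corroboration. Precedence when several kinds fall in one
    window: malfunction > visitor arrival > system change > maintenance
    revert (worst case first). A revert (visitor left, sensor or battery
    replaced) returns to the prevailing single-occupant mode, which is
    upgraded from (1) to (2) permanently once a sensor is added. The first
    segment has no detected change point and takes ``initial_state``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    anns = sorted(annotations, key=lambda a: a.date)
    wspan = timedelta(days=window)
    boundaries = (0,) + segmentation.taus  # 0-based start index per segment
    prevailing = (
        initial_state if initial_state in SINGLE_OCCUPANT_CATEGORIES else "single_occupant_1"
    )
    out: list[SegmentCategory] = []
    for seg_idx, start in enumerate(boundaries, start=1):
        if seg_idx == 1:
            out.append(SegmentCategory(segment=1, category=initial_state))
            continue
        start_date = series.dates[start]
        nearby = tuple(a for a in anns if abs(a.date - start_date) <= wspan and a.kind != "other")
        kinds = {a.kind for a in nearby}
        if kinds & _MALFUNCTION:
            category = "system_malfunction"
        elif "visitor_arrive" in kinds:
            category = "multiple_occupant"
        elif "sensor_add" in kinds:
            prevailing = "single_occupant_2"
            category = "single_occupant_2"
        elif kinds & _REVERT:
            category = prevailing
        else:
            category = "unknown"
            nearby = ()
        out.append(SegmentCategory(segment=seg_idx, category=category, evidence=nearby))
    return out


def day_categories(
    segmentation: Segmentation, categories: Sequence[SegmentCategory]
) -> list[str]:
    """Per-day category labels; every day falls in exactly one segment."""
    bounds = (0,) + segmentation.boundaries
    labels: list[str] = []
    for cat, a, b in zip(categories, bounds, bounds[1:]):
        labels.extend([cat.category] * (b - a))
    return labels


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test on two samples of daily values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values (got {a.size}, {b.size})")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def pairwise_segment_tests(
    series: EntropySeries,
    segmentation: Segmentation,
    categories: Sequence[SegmentCategory],
    alpha: float = 0.01,
    by_segment: bool = True,
) -> dict[tuple[str, str], WelchResult]:
    """Welch tests between groups of days, keyed by pair labels.

    With ``by_segment`` (default) each detected segment is its own group
    labelled ``"<idx>:<category>"`` so that neighbouring regimes can be
    contrasted individually; otherwise days are pooled by category. No
    multiple-testing correction is applied; flag significance against
    ``alpha`` downstream.
    """
    labels = day_categories(segmentation, categories)
    if by_segment:
        bounds = (0,) + segmentation.boundaries
        groups = {
            f"{c.segment}:{c.category}": series.values[a:b]
            for c, a, b in zip(categories, bounds, bounds[1:])
        }
    else:
        groups = {
            cat: series.values[[i for i, l in enumerate(labels) if l == cat]]
            for cat in dict.fromkeys(labels)
        }
    names = [k for k, v in groups.items() if len(v) >= 2]
    out: dict[tuple[str, str], WelchResult] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            out[(na, nb)] = welch_t(groups[na], groups[nb])
    return out


def weekday_weekend(day: _date) -> str:
    return "weekend" if day.weekday() >= 5 else "weekday"


def group_comparison(
    series: EntropySeries,
    day_labeller: Callable[[_date], str] = weekday_weekend,
    restrict_to_days: Iterable[_date] | None = None,
) -> WelchResult:
    """Welch test between two groups of days defined by a labelling rule.

    ``restrict_to_days`` typically holds the days of single-occupant
    segments, so that visitor and malfunction periods do not contaminate
    routine-behaviour contrasts. The labeller must produce exactly two
    labels over the retained days.
    """
    keep = None if restrict_to_days is None else set(restrict_to_days)
    pairs = [
        (day_labeller(d), v)
        for d, v in zip(series.dates, series.values)
        if keep is None or d in keep
    ]
    labels = sorted({l for l, _ in pairs})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 day groups, got {labels}")
    ga = [v for l, v in pairs if l == labels[0]]
    gb = [v for l, v in pairs if l == labels[1]]
    return welch_t(ga, gb)
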