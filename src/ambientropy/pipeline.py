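"""End-to-end orchestration: events -> trajectories -> entropy -> segments.

Stages run in a fixed order — ingest, per-day entropy, isolated-outlier
removal, change-point segmentation, categorization and group tests — and
every run writes a manifest recording the package version, seed, and all
effective parameters so that outputs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .changepoint import best_segmentation, segment_stats, select_k
from .compare import (
    SegmentAnnotation,
    categorize_segments,
    day_categories,
    pairwise_segment_tests,
)
from .entropy import EntropySeries, entropy_record
from .ingest import (
    IngestConfig,
    build_daily_trajectories,
    filter_days,
    read_events,
    remove_isolated_outliers,
    trajectories_to_frame,
)
from .simulate import make_fixture, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    events_path: str | None = None  # mutually exclusive with preset
    preset: str | None = None
    seed: int = 0
    output_dir: str = "ambientropy-out"
    vacation_path: str | None = None
    annotations_path: str | None = None
    min_events: int = 12
    collapse_repeats: bool = True
    outlier_window_days: int = 3
    timezone: str = "UTC"
    k_max: int | None = None  # default: weeks spanned
    l_min: int = 1
    rho: float = 0.75
    hull_only: bool = True
    annotation_window: int = 2
    initial_state: str = "single_occupant_1"
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """YAML config with unknown keys rejected; all fields have defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _read_dates_csv(path) -> list[_date]:
    df = pd.read_csv(path)
    return [d.date() for d in pd.to_datetime(df["date"])]


def _read_annotations(path) -> list[SegmentAnnotation]:
    df = pd.read_csv(path).fillna({"note": ""})
    return [
        SegmentAnnotation(
            date=pd.Timestamp(row.date).date(), kind=str(row.kind), note=str(row.note)
        )
        for row in df.itertuples()
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a result bundle and writes CSV/JSON artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
    }
    bundle: dict = {}

    stage = "ingest"
    try:
        if (config.events_path is None) == (config.preset is None):
            raise ValueError("exactly one of events_path or preset is required")
        if config.preset is not None:
            events, truth = simulate(make_fixture(config.preset, seed=config.seed))
            events.to_csv(out / "events.csv", index=False)
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "change_point_days": truth.change_point_days,
                        "change_point_dates": [str(d) for d in truth.change_point_dates],
                        "regime_kinds": truth.regime_kinds,
                    },
                    indent=2,
                )
            )
            events_path = out / "events.csv"
        else:
            events_path = Path(config.events_path)
            if not events_path.exists():
                raise FileNotFoundError(events_path)
        ingest_cfg = IngestConfig(
            min_events=config.min_events,
            collapse_repeats=config.collapse_repeats,
            outlier_window_days=config.outlier_window_days,
            timezone=config.timezone,
        )
        events = read_events(events_path, ingest_cfg)
        trajectories = build_daily_trajectories(events, config.collapse_repeats)
        vacation = _read_dates_csv(config.vacation_path) if config.vacation_path else []
        kept, report = filter_days(trajectories, vacation, config.min_events)
        if not kept:
            raise ValueError("no days survive the day filters")
        trajectories_to_frame(kept).to_csv(out / "trajectories.csv", index=False)
        pd.DataFrame([dataclasses.asdict(r) for r in report]).to_csv(
            out / "filter_report.csv", index=False
        )
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "entropy"
    try:
        records = [entropy_record(t) for t in kept]
        ent = pd.DataFrame([dataclasses.asdict(r) for r in records])
        ent.to_csv(out / "entropy.csv", index=False)
        series = EntropySeries(
            dates=tuple(r.date for r in records),
            values=np.array([r.s_real for r in records]),
        )
        bundle["entropy"] = ent
        manifest["stages"].append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "outliers"
    try:
        series, rule, removed = remove_isolated_outliers(
            series, config.outlier_window_days
        )
        pd.DataFrame({"removed_date": [str(d) for d in removed]}).to_csv(
            out / "outliers.csv", index=False
        )
        manifest["outlier_rule"] = dataclasses.asdict(rule)
        manifest["stages"].append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "changepoint"
    try:
        selection = select_k(
            series,
            k_max=config.k_max,
            l_min=config.l_min,
            rho=config.rho,
            hull_only=config.hull_only,
        )
        seg = best_segmentation(series, selection.k_hat, config.l_min)
        means, residuals, sds = segment_stats(series, seg)
        bounds = (0,) + seg.boundaries
        pd.DataFrame(
            {
                "segment": range(1, seg.k + 1),
                "start_date": [str(series.dates[a]) for a in bounds[:-1]],
                "end_date": [str(series.dates[b - 1]) for b in bounds[1:]],
                "n_days": [b - a for a, b in zip(bounds, bounds[1:])],
                "mean_entropy": means,
                "sd_entropy": sds,
            }
        ).to_csv(out / "segments.csv", index=False)
        pd.DataFrame(
            {
                "K": range(1, selection.k_max + 1),
                "J_K": selection.contrasts,
                "normalized": selection.normalized,
                "hull_member": selection.hull_member,
                "second_diff": selection.second_diffs,
            }
        ).to_csv(out / "contrast_curve.csv", index=False)
        (out / "segmentation.json").write_text(
            json.dumps(
                {
                    "k_hat": selection.k_hat,
                    "taus": list(seg.taus),
                    "change_point_dates": [str(series.dates[t]) for t in seg.taus],
                    "k_max": selection.k_max,
                    "l_min": selection.l_min,
                    "rho": selection.threshold,
                },
                indent=2,
            )
        )
        bundle.update(series=series, selection=selection, segmentation=seg)
        manifest["stages"].append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "compare"
    try:
        annotations = (
            _read_annotations(config.annotations_path)
            if config.annotations_path
            else []
        )
        categories = categorize_segments(
            series, seg, annotations, config.annotation_window, config.initial_state
        )
        pd.DataFrame(
            {
                "segment": [c.segment for c in categories],
                "category": [c.category for c in categories],
                "evidence_dates": [
                    "|".join(str(a.date) for a in c.evidence) for c in categories
                ],
            }
        ).to_csv(out / "categories.csv", index=False)
        tests = pairwise_segment_tests(series, seg, categories)
        pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "t_stat": r.t_stat,
                    "df": r.df,
                    "p_value": r.p_value,
                    "mean_a": r.mean_a,
                    "mean_b": r.mean_b,
                }
                for (a, b), r in tests.items()
            ]
        ).to_csv(out / "tests.csv", index=False)
        bundle.update(categories=categories, tests=tests)
        manifest["stages"].append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
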