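from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

import ambientropy as amb
from ambientropy.changepoint import best_segmentation
from ambientropy.compare import SegmentAnnotation, day_categories, weekday_weekend
from ambientropy.entropy import EntropySeries


def _series(values, start=date(2018, 6, 5)):
    values = np.asarray(values, dtype=float)
    return EntropySeries(
        dates=tuple(start + timedelta(days=i) for i in range(values.size)),
        values=values,
    )


def _three_segments():
    """Noise-free series with jumps on 2018-08-08 and 2018-11-19."""
    series = _series(np.concatenate([np.full(64, 1.4), np.full(40, 1.1), np.full(30, 1.9)]))
    seg = best_segmentation(series, 3)
    assert [str(series.dates[t]) for t in seg.taus] == ["2018-08-08", "2018-09-17"]
    return series, seg


class TestCategorizeSegments:
    def test_sensor_replace_restores_single_occupant(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(
            series,
            seg,
            [SegmentAnnotation(date(2018, 8, 8), "sensor_replace")],
        )
        assert cats[0].category == "single_occupant_1"  # declared initial state
        assert cats[1].category == "single_occupant_1"  # revert to prevailing mode
        assert cats[2].category == "unknown"

    def test_visitor_arrival_next_day_within_window(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(
            series,
            seg,
            [SegmentAnnotation(date(2018, 9, 18), "visitor_arrive")],
        )
        assert cats[2].category == "multiple_occupant"
        assert cats[2].evidence[0].kind == "visitor_arrive"

    def test_annotation_outside_window_is_unknown(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(
            series,
            seg,
            [SegmentAnnotation(date(2018, 8, 13), "visitor_arrive")],  # 5 days off
            window=2,
        )
        assert cats[1].category == "unknown"
        assert cats[1].evidence == ()

    def test_sensor_add_upgrades_prevailing_mode(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(
            series,
            seg,
            [
                SegmentAnnotation(date(2018, 8, 8), "sensor_add"),
                SegmentAnnotation(date(2018, 9, 17), "battery_replace"),
            ],
        )
        assert cats[1].category == "single_occupant_2"
        # revert after the upgrade returns to mode (2), not (1)
        assert cats[2].category == "single_occupant_2"

    def test_malfunction_takes_precedence(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(
            series,
            seg,
            [
                SegmentAnnotation(date(2018, 8, 8), "battery_drained"),
                SegmentAnnotation(date(2018, 8, 8), "visitor_arrive"),
            ],
        )
        assert cats[1].category == "system_malfunction"

    def test_day_categories_partition(self):
        series, seg = _three_segments()
        cats = amb.categorize_segments(series, seg, [])
        labels = day_categories(seg, cats)
        assert len(labels) == series.n  # every day in exactly one category


class TestWelchT:
    def test_identical_groups(self):
        r = amb.welch_t([1, 2, 3], [1, 2, 3])
        assert r.t_stat == 0.0 and r.p_value == 1.0

    def test_clear_separation(self):
        r = amb.welch_t([2.1, 2.0, 1.9, 2.0], [1.0, 1.1, 0.9, 1.0])
        assert r.p_value < 0.001

    def test_matches_closed_form(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 17)
        r = amb.welch_t(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert r.t_stat == pytest.approx(t)
        assert r.df == pytest.approx(df)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), df))

    def test_symmetry(self):
        rng = np.random.default_rng(32)
        a, b = rng.normal(size=10), rng.normal(size=15)
        r1, r2 = amb.welch_t(a, b), amb.welch_t(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.t_stat == pytest.approx(-r2.t_stat)

    def test_shaped_on_adjacent_regimes(self):
        """Groups shaped like two adjacent regimes (means 1.48/1.18, SDs
        0.16/0.14, n 31/33) separate at far below 0.001 in most draws."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(600 + s)
            r = amb.welch_t(rng.normal(1.48, 0.16, 31), rng.normal(1.18, 0.14, 33))
            hits += r.p_value < 1e-6
        assert hits >= 15

    def test_undersized_group_errors(self):
        with pytest.raises(ValueError):
            amb.welch_t([1.0], [1.0, 2.0])


class TestPairwiseTests:
    def test_power_at_one_sigma_gap(self):
        rng = np.random.default_rng(71)
        series = _series(
            np.concatenate([rng.normal(1.5, 0.15, 50), rng.normal(1.65, 0.15, 50)])
        )
        seg = best_segmentation(series, 2)
        cats = amb.categorize_segments(
            series, seg, [SegmentAnnotation(series.dates[50], "visitor_arrive")]
        )
        tests = amb.pairwise_segment_tests(series, seg, cats)
        assert len(tests) == 1
        assert next(iter(tests.values())).p_value < 0.01

    def test_single_segment_empty_matrix(self):
        series = _series(np.random.default_rng(72).normal(size=30))
        seg = best_segmentation(series, 1)
        cats = amb.categorize_segments(series, seg, [])
        assert amb.pairwise_segment_tests(series, seg, cats) == {}

    def test_type_one_error_rate_at_alpha(self):
        """Identical-by-construction groups: flagged at 0.01 rarely."""
        false_hits = 0
        for s in range(50):
            rng = np.random.default_rng(800 + s)
            series = _series(rng.normal(1.5, 0.15, 60))
            seg = amb.Segmentation(
                k=2, taus=(30,), means=(0, 0), residuals=np.zeros(60), contrast=0.0
            )
            cats = amb.categorize_segments(
                series, seg, [SegmentAnnotation(series.dates[30], "visitor_arrive")]
            )
            tests = amb.pairwise_segment_tests(series, seg, cats)
            false_hits += any(r.p_value < 0.01 for r in tests.values())
        assert false_hits <= 5  # >= 90% of seeds show no false flag


class TestGroupComparison:
    def test_null_parity_split_is_uniformish(self):
        pvals = []
        for s in range(40):
            rng = np.random.default_rng(900 + s)
            series = _series(rng.normal(1.5, 0.15, 120))
            r = amb.group_comparison(
                series, lambda d: "even" if d.toordinal() % 2 == 0 else "odd"
            )
            pvals.append(r.p_value)
        assert 0.2 < np.mean(np.array(pvals) < 0.5) < 0.8

    def test_planted_weekend_effect_detected(self):
        hits = 0
        for s in range(11):
            rng = np.random.default_rng(950 + s)
            vals = np.array(
                [
                    rng.normal(1.5 + (0.3 if weekday_weekend(date(2018, 1, 1) + timedelta(days=i)) == "weekend" else 0.0), 0.15)
                    for i in range(200)
                ]
            )
            series = _series(vals, start=date(2018, 1, 1))
            hits += amb.group_comparison(series).p_value < 0.01
        assert hits > 5  # majority of seeds

    def test_restriction_to_day_subset(self):
        series = _series(np.arange(20.0))
        keep = series.dates[:14]
        r = amb.group_comparison(series, weekday_weekend, restrict_to_days=keep)
        assert r.n_a + r.n_b == 14

    def test_single_group_errors(self):
        series = _series(np.random.default_rng(1).normal(size=10))
        with pytest.raises(ValueError):
            amb.group_comparison(series, lambda d: "all")
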