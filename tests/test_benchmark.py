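"""Confusion counting, sensitivity/precision, sweeps and threshold selection."""

import numpy as np
import pytest

from btspred.benchmark import (
    BenchmarkCurve,
    ConfusionCounts,
    CurvePoint,
    compare_predictors,
    confusion,
    precision,
    select_threshold,
    sensitivity,
    sweep_thresholds,
)


def counts(tp=0, fp=0, fn=0, tn=0):
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           positive_class="plastid", threshold=1.0)


class TestMetrics:
    def test_sensitivity_is_tp_over_tp_plus_fn(self):
        assert sensitivity(counts(tp=3, fn=1)) == pytest.approx(0.75)
        assert sensitivity(counts(tp=0, fn=5)) == 0.0

    def test_precision_is_tp_over_tp_plus_fp(self):
        assert precision(counts(tp=3, fp=1)) == pytest.approx(0.75)
        assert precision(counts(tp=5, fp=0)) == 1.0

    def test_undefined_metrics_return_markers_never_numbers(self):
        assert sensitivity(counts(tn=4)) is None
        assert precision(counts(fn=4)) is None


class TestConfusion:
    def test_counting_at_threshold(self):
        scores = {"a": 2.0, "b": 2.0, "c": 2.0, "d": 0.5, "e": 3.0, "f": 0.1}
        truth = {k: "plastid" for k in "abcd"} | {"e": "cytosol", "f": "cytosol"}
        c = confusion(scores, truth, "plastid", threshold=1.0)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 1)
        assert c.total == 6

    def test_empty_maps_give_zero_counts(self):
        c = confusion({}, {}, "plastid", 1.0)
        assert c.total == 0

    def test_id_mismatch_lists_symmetric_difference(self):
        with pytest.raises(KeyError, match="extra.*missing|missing.*extra"):
            confusion({"a": 1.0, "extra": 2.0},
                      {"a": "plastid", "missing": "cytosol"}, "plastid", 1.0)

    def test_random_cohort_matches_independent_tally(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(50)]
        scores = {i: float(rng.normal()) for i in ids}
        truth = {i: ("plastid" if rng.random() < 0.4 else "other") for i in ids}
        for t in (-1.0, 0.0, 0.7):
            c = confusion(scores, truth, "plastid", t)
            tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
            for i in ids:
                pos, hit = truth[i] == "plastid", scores[i] >= t
                tally["tp" if pos and hit else
                      "fn" if pos else
                      "fp" if hit else "tn"] += 1
            assert (c.tp, c.fp, c.fn, c.tn) == (
                tally["tp"], tally["fp"], tally["fn"], tally["tn"]
            )


class TestSweep:
    def _random_cohort(self, seed=9, n=50):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        scores = {i: float(np.round(rng.normal(), 2)) for i in ids}
        truth = {i: ("plastid" if rng.random() < 0.5 else "other") for i in ids}
        return scores, truth

    def test_perfect_separation_reaches_perfect_point(self):
        scores = {"a": 5.0, "b": 6.0, "c": 1.0, "d": 0.0}
        truth = {"a": "plastid", "b": "plastid", "c": "other", "d": "other"}
        curve = sweep_thresholds(scores, truth, "plastid")
        assert any(p.sensitivity == 1.0 and p.precision == 1.0
                   for p in curve.points)

    def test_all_positive_cohort_has_precision_one_everywhere_defined(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0}
        truth = {k: "plastid" for k in scores}
        curve = sweep_thresholds(scores, truth, "plastid")
        assert all(p.precision in (None, 1.0) for p in curve.points)

    def test_pointwise_equal_to_per_threshold_confusion(self):
        scores, truth = self._random_cohort()
        curve = sweep_thresholds(scores, truth, "plastid")
        for p in curve.points:
            c = confusion(scores, truth, "plastid", p.threshold)
            assert (p.counts.tp, p.counts.fp) == (c.tp, c.fp)
            assert p.sensitivity == sensitivity(c)
            assert p.precision == precision(c)

    def test_sensitivity_weakly_decreasing_along_curve(self):
        scores, truth = self._random_cohort(seed=21)
        curve = sweep_thresholds(scores, truth, "plastid")
        sens = [p.sensitivity for p in curve.points if p.sensitivity is not None]
        assert all(b <= a + 1e-12 for a, b in zip(sens, sens[1:]))
        called = [p.counts.tp + p.counts.fp for p in curve.points]
        assert all(b <= a for a, b in zip(called, called[1:]))

    def test_single_distinct_score_yields_single_point_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            curve = sweep_thresholds({"a": 1.0, "b": 1.0},
                                     {"a": "plastid", "b": "other"}, "plastid")
        assert len(curve.points) == 1
        assert any("single-point" in m for m in caplog.messages)


def curve_from(points):
    pts = tuple(
        CurvePoint(threshold=t, sensitivity=s, precision=p,
                   counts=counts(tp=1, fn=1))
        for t, s, p in points
    )
    return BenchmarkCurve(points=pts, predictor="x", positive_class="plastid")


class TestSelectThreshold:
    def test_sensitivity_floor_picks_largest_qualifying_threshold(self):
        curve = curve_from([(0.5, 0.95, 0.60), (1.4, 0.83, 0.92),
                            (2.0, 0.70, 0.95)])
        sel = select_threshold(curve, "sensitivity_level", 0.75)
        assert sel.threshold == 1.4 and sel.attainable
        assert sel.sensitivity == 0.83

    def test_precision_floor_picks_smallest_qualifying_threshold(self):
        curve = curve_from([(0.5, 0.95, 0.60), (1.4, 0.83, 0.92),
                            (2.0, 0.70, 0.95)])
        sel = select_threshold(curve, "precision_level", 0.85)
        assert sel.threshold == 1.4 and sel.attainable

    def test_unattainable_floor_returns_flagged_closest_point(self):
        curve = curve_from([(0.5, 0.9, 0.40), (1.0, 0.8, 0.55), (2.0, 0.5, 0.60)])
        sel = select_threshold(curve, "precision_level", 0.85)
        assert not sel.attainable and sel.precision == 0.60

    def test_single_point_curve_selected_in_both_modes(self):
        curve = curve_from([(1.0, 0.8, 0.9)])
        for mode in ("sensitivity_level", "precision_level"):
            sel = select_threshold(curve, mode, 0.75)
            assert sel.threshold == 1.0

    def test_selected_point_lies_on_the_curve(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(60)]
        scores = {i: float(rng.normal()) for i in ids}
        truth = {i: ("plastid" if rng.random() < 0.5 else "other") for i in ids}
        curve = sweep_thresholds(scores, truth, "plastid")
        for mode, level in (("sensitivity_level", 0.75), ("precision_level", 0.85)):
            sel = select_threshold(curve, mode, level)
            assert any(
                p.threshold == sel.threshold
                and p.sensitivity == sel.sensitivity
                and p.precision == sel.precision
                for p in curve.points
            )


class TestComparePredictors:
    def test_perfect_predictor_reports_perfect_metrics(self):
        scores = {"a": 9.0, "b": 8.0, "c": 0.1}
        truth = {"a": "plastid", "b": "plastid", "c": "other"}
        report = compare_predictors({"perfect": scores}, truth, "plastid")
        row = report.iloc[0]
        assert row.s_sensitivity == 1.0 and row.p_precision == 1.0

    def test_dominated_predictor_never_beats_the_dominant_one(self):
        rng = np.random.default_rng(17)
        ids = [f"p{i}" for i in range(100)]
        truth = {i: ("plastid" if rng.random() < 0.5 else "other") for i in ids}
        # dominant: high separation; dominated: same scores + heavy noise
        good = {
            i: (2.0 if truth[i] == "plastid" else 0.0) + float(rng.normal(0, 0.2))
            for i in ids
        }
        bad = {i: good[i] + float(rng.normal(0, 3.0)) for i in ids}
        report = compare_predictors({"good": good, "bad": bad}, truth, "plastid")
        r = report.set_index("predictor")
        assert r.loc["good", "s_precision"] >= r.loc["bad", "s_precision"]
        assert r.loc["good", "p_sensitivity"] >= r.loc["bad", "p_sensitivity"]
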