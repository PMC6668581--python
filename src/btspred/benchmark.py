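"""Sensitivity/precision benchmarking and dual-threshold selection.

Predictors are compared by sweeping a score threshold and computing, per
positive class (one-vs-rest),

    sensitivity = TP / (TP + FN)        (recall of the positive class)
    precision   = TP / (TP + FP)        (positive predictive value)

with the inclusive convention that a score *passes* a threshold when
``score >= threshold``.  Two operating points are then selected per
predictor: an *s*-threshold aimed at a sensitivity floor (default 75%) and
a *p*-threshold aimed at a precision floor (default 85%).  Undefined
metrics (empty denominators) surface as explicit ``None`` markers, never as
0 or 1, so they cannot silently inflate a curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str
    threshold: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    sensitivity: Optional[float]
    precision: Optional[float]
    counts: ConfusionCounts


@dataclass(frozen=True)
class BenchmarkCurve:
    points: tuple[CurvePoint, ...]
    predictor: str
    positive_class: str

    def __post_init__(self) -> None:
        thresholds = [p.threshold for p in self.points]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("curve thresholds must be strictly increasing")


@dataclass(frozen=True)
class SelectedThreshold:
    threshold: float
    sensitivity: Optional[float]
    precision: Optional[float]
    attainable: bool


def confusion(
    scores: Mapping[str, float],
    truth: Mapping[str, str],
    positive_class: str,
    threshold: float,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN at a threshold (``score >= threshold`` is a call).

    ``scores`` and ``truth`` must cover exactly the same ids.
    """
    if set(scores) != set(truth):
        diff = sorted(set(scores) ^ set(truth))
        raise KeyError(f"score/truth id mismatch; symmetric difference: {diff}")
    tp = fp = fn = tn = 0
    for rid, score in scores.items():
        is_positive = truth[rid] == positive_class
        called = score >= threshold
        if is_positive and called:
            tp += 1
        elif is_positive:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=tn,
        positive_class=positive_class, threshold=threshold,
    )


def sensitivity(counts: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FN); ``None`` (undefined marker) when there are no positives."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return None
    return counts.tp / denom


def precision(counts: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FP); ``None`` (undefined marker) when nothing was called."""
    denom = counts.tp + counts.fp
    if denom == 0:
        return None
    return counts.tp / denom


def sweep_thresholds(
    scores: Mapping[str, float],
    truth: Mapping[str, str],
    positive_class: str,
    grid: Optional[Sequence[float]] = None,
    predictor: str = "scores",
) -> BenchmarkCurve:
    """Benchmark curve with one point per threshold.

    The grid defaults to the sorted unique scores, so every achievable
    operating point appears exactly once.  Points with undefined precision
    are kept (flagged by ``None``), never dropped.
    """
    if grid is None:
        grid = sorted(set(scores.values()))
    else:
        grid = sorted(set(grid))
    if len(grid) < 2:
        log.warning(
            "sweep over %r: fewer than 2 distinct thresholds; single-point curve",
            predictor,
        )
    points = []
    for t in grid:
        counts = confusion(scores, truth, positive_class, t)
        points.append(
            CurvePoint(
                threshold=t,
                sensitivity=sensitivity(counts),
                precision=precision(counts),
                counts=counts,
            )
        )
    return BenchmarkCurve(
        points=tuple(points), predictor=predictor, positive_class=positive_class
    )


def select_threshold(
    curve: BenchmarkCurve, mode: str, level: float
) -> SelectedThreshold:
    """Select an operating point from a curve.

    ``sensitivity_level``: the largest threshold whose sensitivity is still
    >= ``level`` (sensitivity falls as the threshold rises, so this
    maximizes precision subject to the sensitivity floor).
    ``precision_level``: the smallest threshold whose precision is >=
    ``level`` (maximizing sensitivity subject to the precision floor).
    If the floor is unattainable, the closest point is returned flagged
    ``attainable=False``.
    """
    if not curve.points:
        raise ValueError("cannot select from an empty curve")
    if not (0 < level <= 1):
        raise ValueError("level must lie in (0, 1]")
    if mode == "sensitivity_level":
        eligible = [p for p in curve.points if p.sensitivity is not None
                    and p.sensitivity >= level]
        if eligible:
            best = max(eligible, key=lambda p: p.threshold)
            return SelectedThreshold(best.threshold, best.sensitivity,
                                     best.precision, True)
        defined = [p for p in curve.points if p.sensitivity is not None]
        pool = defined or list(curve.points)
        best = min(pool, key=lambda p: (abs((p.sensitivity or 0.0) - level),
                                        p.threshold))
        return SelectedThreshold(best.threshold, best.sensitivity,
                                 best.precision, False)
    if mode == "precision_level":
        eligible = [p for p in curve.points if p.precision is not None
                    and p.precision >= level]
        if eligible:
            best = min(eligible, key=lambda p: p.threshold)
            return SelectedThreshold(best.threshold, best.sensitivity,
                                     best.precision, True)
        defined = [p for p in curve.points if p.precision is not None]
        pool = defined or list(curve.points)
        best = min(pool, key=lambda p: (abs((p.precision or 0.0) - level),
                                        p.threshold))
        return SelectedThreshold(best.threshold, best.sensitivity,
                                 best.precision, False)
    raise ValueError(f"unknown mode {mode!r}")


def compare_predictors(
    score_tables: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, str],
    positive_class: str,
    levels: tuple[float, float] = (0.75, 0.85),
) -> pd.DataFrame:
    """Per-predictor dual-threshold report.

    For every predictor, sweep its scores and select the s-threshold
    (sensitivity floor ``levels[0]``) and p-threshold (precision floor
    ``levels[1]``).  Returns a tidy DataFrame, one row per predictor.
    """
    if not score_tables:
        raise ValueError("need at least one predictor score table")
    sens_level, prec_level = levels
    rows = []
    for name, scores in score_tables.items():
        curve = sweep_thresholds(scores, truth, positive_class, predictor=name)
        s_pt = select_threshold(curve, "sensitivity_level", sens_level)
        p_pt = select_threshold(curve, "precision_level", prec_level)
        rows.append(
            {
                "predictor": name,
                "positive_class": positive_class,
                "s_threshold": s_pt.threshold,
                "s_sensitivity": s_pt.sensitivity,
                "s_precision": s_pt.precision,
                "s_attainable": s_pt.attainable,
                "p_threshold": p_pt.threshold,
                "p_sensitivity": p_pt.sensitivity,
                "p_precision": p_pt.precision,
                "p_attainable": p_pt.attainable,
            }
        )
    return pd.DataFrame(rows)
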