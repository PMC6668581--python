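"""High-level workflows tying training, scanning and benchmarking together.

These are the entry points the CLI, the examples and the acceptance checks
use: train the species-specific models from a labelled reference set, run
the classifier over a proteome, and calibrate a plastid threshold by a
sensitivity-floor sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import benchmark as bm
from .cleavage import (
    DEFAULT_PWM_OFFSETS,
    SignalPWM,
    predict_cleavage_pwm,
    train_signal_pwm,
)
from .matrix import (
    DEFAULT_MATRIX_OFFSETS,
    BitScoreMatrix,
    build_window_stack,
    compute_bitscore_matrix,
)
from .scanner import PredictionResult, classify
from .seqio import ReferenceEntry, SequenceRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainedModels:
    pwm: SignalPWM
    matrix: BitScoreMatrix


def train_models(
    entries: Iterable[ReferenceEntry],
    pwm_offsets: range = DEFAULT_PWM_OFFSETS,
    matrix_offsets: range = DEFAULT_MATRIX_OFFSETS,
    pseudocount: float = 1.0,
    species_tag: str = "",
) -> TrainedModels:
    """Train the cleavage-site PWM and the plastid bit-score matrix.

    The PWM is trained on every signal-bearing entry (plastid + secretory)
    with a known cleavage site; the bit-score matrix only on the plastid
    entries, whose post-cleavage windows carry the transit-peptide motif.
    Excluded entries are dropped.
    """
    entries = [e for e in entries if not e.excluded]
    signal_bearing = [
        e for e in entries
        if e.known_cleavage is not None and e.label in ("plastid", "secretory")
    ]
    pwm = train_signal_pwm(signal_bearing, offsets=pwm_offsets,
                           pseudocount=pseudocount)
    plastid = [(e.record, e.known_cleavage) for e in entries
               if e.label == "plastid" and e.known_cleavage is not None]
    stack = build_window_stack(plastid, offsets=matrix_offsets)
    matrix = compute_bitscore_matrix(stack, species_tag=species_tag)
    return TrainedModels(pwm=pwm, matrix=matrix)


def classify_records(
    records: Iterable[SequenceRecord],
    models: TrainedModels,
    plastid_threshold: float,
    mito_scores: Optional[Mapping[str, float]] = None,
    mito_threshold: float = 0.5,
    pwm_min_score: float = 0.0,
) -> list[PredictionResult]:
    """Run the full cascade (PWM cleavage -> window scan -> call) per record."""
    results = []
    for rec in records:
        site = predict_cleavage_pwm(rec, models.pwm, min_score=pwm_min_score)
        mito = None if mito_scores is None else mito_scores.get(rec.id)
        results.append(
            classify(rec, site, models.matrix, plastid_threshold,
                     mito_score=mito, mito_threshold=mito_threshold)
        )
    return results


def plastid_score_table(
    records: Iterable[SequenceRecord],
    models: TrainedModels,
    pwm_min_score: float = 0.0,
    require_agreement: bool = True,
) -> dict[str, float]:
    """Cumulative transit-peptide score per record, for threshold sweeps.

    Records with no predicted cleavage site — or whose best scan window
    disagrees with it, when ``require_agreement`` — score minus infinity is
    unusable in a sweep, so they get a score below every real one (the
    minimum finite score minus 1), representing "never called plastid".
    """
    from .scanner import ScanError, scan_windows

    raw: dict[str, Optional[float]] = {}
    for rec in records:
        site = predict_cleavage_pwm(rec, models.pwm, min_score=pwm_min_score)
        if site is None:
            raw[rec.id] = None
            continue
        try:
            scan = scan_windows(rec, site, models.matrix)
        except ScanError:
            raw[rec.id] = None
            continue
        if require_agreement and not scan.agrees:
            raw[rec.id] = None
        else:
            raw[rec.id] = scan.cumulative_score
    finite = [v for v in raw.values() if v is not None]
    floor = (min(finite) if finite else 0.0) - 1.0
    return {k: (floor if v is None else v) for k, v in raw.items()}


def calibrate_threshold(
    records: Iterable[SequenceRecord],
    truth: Mapping[str, str],
    models: TrainedModels,
    sensitivity_floor: float = 0.75,
    positive_class: str = "plastid",
) -> bm.SelectedThreshold:
    """Pick the plastid threshold: largest threshold keeping sensitivity at
    or above the floor (maximizing precision subject to it)."""
    scores = plastid_score_table(records, models)
    curve = bm.sweep_thresholds(scores, truth, positive_class,
                                predictor="btspred")
    return bm.select_threshold(curve, "sensitivity_level", sensitivity_floor)
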