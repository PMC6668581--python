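"""Adapters for external localization-predictor output tables.

Established predictors (TargetP, SignalP, HECTAR, MultiLoc2, PrediSi,
PredSL) each emit their own tab-separated report; this module normalizes
such reports into :class:`ExternalPrediction` rows and plain id->score maps
that plug directly into the benchmarking and consensus machinery.  Native
formats drift between tool versions, so only the documented ``generic``
dialect (header ``id  score  cleavage  call``) is guaranteed; the per-tool
dialects are best-effort column mappings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .cleavage import CleavageSite

log = logging.getLogger(__name__)

PREDICTORS = frozenset(
    {"targetp", "signalp", "hectar", "multiloc2", "predisi", "predsl", "generic"}
)

#: dialect -> column-name mapping onto (id, score, cleavage, call).
#: Cleavage/call columns may be absent in a tool's report.
DIALECTS: dict[str, dict[str, Optional[str]]] = {
    "generic": {"id": "id", "score": "score", "cleavage": "cleavage", "call": "call"},
    "signalp": {"id": "name", "score": "D", "cleavage": "pos", "call": None},
    "targetp": {"id": "name", "score": "mTP", "cleavage": "TPlen", "call": "Loc"},
    "hectar": {"id": "protein id", "score": "signal peptide score",
               "cleavage": None, "call": "predicted targeting category"},
    "multiloc2": {"id": "id", "score": "mitochondrial", "cleavage": None,
                  "call": "prediction"},
    "predisi": {"id": "FASTA-ID", "score": "Score", "cleavage": "Cleavage Position",
                "call": None},
    "predsl": {"id": "id", "score": "SP score", "cleavage": "cleavage site",
               "call": "prediction"},
}


class PredictorTableError(ValueError):
    """Raised with a full summary of every malformed row in a table."""

    def __init__(self, path, bad_rows: list[tuple[int, str]]):
        self.bad_rows = bad_rows
        lines = "; ".join(f"line {n}: {msg}" for n, msg in bad_rows)
        super().__init__(f"{path}: {len(bad_rows)} malformed row(s): {lines}")


@dataclass(frozen=True)
class ExternalPrediction:
    record_id: str
    predictor: str
    score: float
    cleavage_position: Optional[int] = None
    raw_call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"{self.record_id}: score must be finite")


def parse_predictor_table(
    path: str | Path,
    dialect: str = "generic",
    predictor: Optional[str] = None,
    strict: bool = True,
) -> list[ExternalPrediction]:
    """Parse one external predictor's TSV report.

    Rows failing numeric parse are collected with their line numbers; in
    strict mode (default) any bad row aborts with a
    :class:`PredictorTableError` listing *every* offender, so a file either
    parses fully or the report is complete.  ``strict=False`` instead skips
    bad rows with a logged summary.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    predictor = predictor or (dialect if dialect in PREDICTORS else "generic")
    path = Path(path)
    predictions: list[ExternalPrediction] = []
    bad: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in (mapping["id"], mapping["score"])
                   if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing} "
                             f"for dialect {dialect!r}")
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get(mapping["id"]) or "").strip()
            if not rid:
                bad.append((lineno, "empty id"))
                continue
            try:
                score = float((row.get(mapping["score"]) or "").strip())
            except ValueError:
                bad.append((lineno, f"score {row.get(mapping['score'])!r} "
                                    "is not a number"))
                continue
            cleavage: Optional[int] = None
            col = mapping["cleavage"]
            if col and (row.get(col) or "").strip():
                try:
                    cleavage = int(float(row[col].strip()))
                except ValueError:
                    bad.append((lineno, f"cleavage {row[col]!r} is not an integer"))
                    continue
            call_col = mapping["call"]
            raw_call = (row.get(call_col) or "").strip() or None if call_col else None
            try:
                predictions.append(
                    ExternalPrediction(
                        record_id=rid, predictor=predictor, score=score,
                        cleavage_position=cleavage, raw_call=raw_call,
                    )
                )
            except ValueError as exc:
                bad.append((lineno, str(exc)))
    if bad:
        if strict:
            raise PredictorTableError(path, bad)
        log.warning("%s: skipped %d malformed row(s): %s", path, len(bad), bad)
    if not predictions and not bad:
        raise ValueError(f"{path}: no data rows")
    return predictions


def to_score_table(
    predictions: Iterable[ExternalPrediction],
    predictor: Optional[str] = None,
) -> dict[str, float]:
    """Collapse predictions from a single predictor into an id->score map
    (the input expected by :func:`btspred.benchmark.sweep_thresholds`)."""
    table: dict[str, float] = {}
    names = set()
    for p in predictions:
        names.add(p.predictor)
        if predictor is not None and p.predictor != predictor:
            raise ValueError(
                f"prediction for {p.record_id!r} is from {p.predictor!r}, "
                f"expected {predictor!r}"
            )
        if p.record_id in table:
            raise ValueError(f"duplicate prediction for id {p.record_id!r}")
        table[p.record_id] = p.score
    if len(names) > 1:
        raise ValueError(f"mixed predictors in one table: {sorted(names)}")
    return table


def to_cleavage_sites(
    predictions: Iterable[ExternalPrediction],
) -> dict[str, CleavageSite]:
    """Extract per-record cleavage sites (where reported) for consensus calling."""
    sites: dict[str, CleavageSite] = {}
    for p in predictions:
        if p.cleavage_position is None:
            continue
        if p.record_id in sites:
            raise ValueError(f"duplicate cleavage site for id {p.record_id!r}")
        sites[p.record_id] = CleavageSite(
            record_id=p.record_id, position=p.cleavage_position,
            predictor=p.predictor, score=p.score,
        )
    return sites
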