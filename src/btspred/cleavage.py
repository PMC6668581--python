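"""Signal-peptide cleavage-site prediction and multi-predictor consensus.

The bipartite targeting signal starts with a classic ER signal peptide; its
cleavage site anchors everything downstream (matrix training windows, the
transit-peptide scan).  Two pieces live here:

* a self-contained position-weight-matrix (PWM) cleavage-site predictor in
  the PrediSi/PredSL family — log2 odds of residue frequencies around known
  cleavage sites over a background — trained on labelled references;
* a consensus caller that combines the (possibly disagreeing) cleavage
  sites of several predictors by strict majority vote, the rule used to
  select training sites for the bit-score matrices.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, ReferenceEntry, SequenceRecord

log = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default PWM window relative to the cleavage site: the classic signal
#: peptidase footprint, 13 residues into the signal peptide (offset 0 is the
#: last signal-peptide residue) through 2 residues of the mature protein.
DEFAULT_PWM_OFFSETS = range(-13, 3)

#: Default candidate cleavage positions: signal peptides of BTS-bearing
#: proteins end well within the first ~45 residues, while positions below 10
#: cannot hold a complete signal peptide.
DEFAULT_SEARCH_RANGE = range(10, 46)


@dataclass(frozen=True)
class CleavageSite:
    """A predicted signal-peptide cleavage site.

    ``position`` is the 1-based index of the LAST residue of the signal
    peptide, so the mature protein starts at ``position + 1``.
    """

    record_id: str
    position: int
    predictor: str
    score: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("cleavage position must be >= 1")
        if not self.predictor:
            raise ValueError("predictor name must be non-empty")


@dataclass(frozen=True)
class SignalPWM:
    """Log-odds matrix over a fixed offset window around the cleavage site.

    ``cells[i, j]`` is log2(freq / background) for offset ``offsets[i]`` and
    residue ``AMINO_ACIDS[j]``.  X never contributes to training or scoring.
    """

    offsets: tuple[int, ...]
    cells: np.ndarray  # shape (n_offsets, 20)
    background: np.ndarray  # shape (20,), sums to 1
    pseudocount: float
    n_train: int

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.offsets), 20):
            raise ValueError("cells shape does not match offsets")
        if not np.all(np.isfinite(self.cells)):
            raise ValueError("PWM cells must all be finite")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def cell(self, offset: int, residue: str) -> float:
        """Log-odds of ``residue`` at ``offset``; X scores 0."""
        if residue == "X":
            return 0.0
        return float(self.cells[self.offsets.index(offset), _AA_INDEX[residue]])


def uniform_background() -> np.ndarray:
    """Uniform background: every standard residue at frequency 0.05."""
    return np.full(20, 0.05)


def background_from_records(records: Iterable[SequenceRecord]) -> np.ndarray:
    """Estimate background residue frequencies from sequences (X ignored)."""
    counts = Counter()
    for rec in records:
        counts.update(c for c in rec.residues if c != "X")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues to estimate a background from")
    return np.array([counts[a] / total for a in AMINO_ACIDS])


def train_signal_pwm(
    entries: Iterable[ReferenceEntry],
    offsets: range | Sequence[int] = DEFAULT_PWM_OFFSETS,
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
) -> SignalPWM:
    """Train a cleavage-site PWM from entries with known cleavage positions.

    For offset ``o`` and residue ``a``::

        cell(o, a) = log2( (count(a at o) + pseudocount)
                           / (n_o + 20 * pseudocount) / background(a) )

    where ``n_o`` counts non-X residues observed at offset ``o``.  Entries
    without a known cleavage site, or too short to cover the full window,
    are skipped with a warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (keeps all cells finite)")
    offs = tuple(offsets)
    if not offs:
        raise ValueError("offset window must be non-empty")
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)

    counts = np.zeros((len(offs), 20))
    n_used = 0
    for entry in entries:
        if entry.known_cleavage is None:
            log.warning("entry %r has no known cleavage; skipped", entry.record.id)
            continue
        pos = entry.known_cleavage
        residues = entry.record.residues
        lo, hi = pos + offs[0], pos + offs[-1]
        if lo < 1 or hi > len(residues):
            log.warning(
                "entry %r does not cover offsets %d..%d around cleavage %d; skipped",
                entry.record.id, offs[0], offs[-1], pos,
            )
            continue
        for i, o in enumerate(offs):
            residue = residues[pos + o - 1]  # 1-based indexing
            if residue != "X":
                counts[i, _AA_INDEX[residue]] += 1
        n_used += 1
    if n_used < 2:
        raise ValueError(f"need >= 2 usable training entries, got {n_used}")

    n_per_offset = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount) / (n_per_offset + 20 * pseudocount)
    cells = np.log2(freq / background)
    return SignalPWM(
        offsets=offs,
        cells=cells,
        background=background,
        pseudocount=pseudocount,
        n_train=n_used,
    )


def score_position(record: SequenceRecord, pwm: SignalPWM, position: int) -> float:
    """PWM score of a candidate cleavage position (sum over the window)."""
    total = 0.0
    for i, o in enumerate(pwm.offsets):
        residue = record.residues[position + o - 1]
        if residue != "X":
            total += float(pwm.cells[i, _AA_INDEX[residue]])
    return total


def predict_cleavage_pwm(
    record: SequenceRecord,
    pwm: SignalPWM,
    search_range: range | Sequence[int] = DEFAULT_SEARCH_RANGE,
    min_score: float = 0.0,
) -> Optional[CleavageSite]:
    """Scan candidate positions and return the best-scoring cleavage site.

    Candidate positions whose PWM window would fall outside the sequence are
    dropped; if none remain, or the best score is below ``min_score``, the
    result is absent (None).  Ties break to the smallest position.
    """
    candidates = [
        p
        for p in search_range
        if p + pwm.offsets[0] >= 1 and p + pwm.offsets[-1] <= len(record)
    ]
    if not candidates:
        return None
    best_pos, best_score = None, -math.inf
    for p in candidates:
        s = score_position(record, pwm, p)
        if s > best_score:  # strict: first (smallest) position wins ties
            best_pos, best_score = p, s
    if best_score < min_score:
        return None
    return CleavageSite(
        record_id=record.id, position=best_pos, predictor="pwm", score=best_score
    )


def consensus_cleavage(
    sites: Iterable[Optional[CleavageSite]],
    tolerance: int = 0,
) -> Optional[CleavageSite]:
    """Call a consensus cleavage site by strict majority vote.

    Let ``k`` be the number of predictors that returned any site.  A position
    wins if supported by more than ``k/2`` of them; the returned site carries
    ``predictor="consensus"`` and ``score`` = number of supporters.  With no
    strict majority the result is absent.  ``tolerance`` > 0 lets positions
    within that distance count as agreement (off by default: the strict
    reading requires exact identity).
    """
    reported = [s for s in sites if s is not None]
    if not reported:
        return None
    predictors = [s.predictor for s in reported]
    dupes = [p for p, c in Counter(predictors).items() if c > 1]
    if dupes:
        raise ValueError(f"multiple sites from the same predictor(s): {dupes}")
    record_ids = {s.record_id for s in reported}
    if len(record_ids) > 1:
        raise ValueError(f"sites refer to different records: {sorted(record_ids)}")
    k = len(reported)
    positions = sorted({s.position for s in reported})
    best_pos, best_support = None, 0
    for p in positions:
        support = sum(1 for s in reported if abs(s.position - p) <= tolerance)
        if support > best_support:
            best_pos, best_support = p, support
    if best_support * 2 <= k:
        return None
    return CleavageSite(
        record_id=reported[0].record_id,
        position=best_pos,
        predictor="consensus",
        score=float(best_support),
    )


# --- TSV serialization -----------------------------------------------------

def write_pwm(pwm: SignalPWM, path: str | Path) -> None:
    """Serialize a PWM as TSV: '#' metadata header, rows = offsets."""
    with open(path, "w") as fh:
        fh.write(f"# n_train\t{pwm.n_train}\n")
        fh.write(f"# pseudocount\t{pwm.pseudocount!r}\n")
        fh.write("# background\t" + "\t".join(repr(float(b)) for b in pwm.background) + "\n")
        fh.write("offset\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, o in enumerate(pwm.offsets):
            fh.write(str(o) + "\t" + "\t".join(repr(float(c)) for c in pwm.cells[i]) + "\n")


def read_pwm(path: str | Path) -> SignalPWM:
    """Read a PWM written by :func:`write_pwm`."""
    meta: dict[str, str] = {}
    offsets: list[int] = []
    rows: list[list[float]] = []
    background: Optional[np.ndarray] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "background":
                    background = np.array([float(x) for x in parts[1:]])
                else:
                    meta[parts[0]] = parts[1]
            elif line.startswith("offset"):
                continue
            else:
                parts = line.split("\t")
                offsets.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
    if background is None:
        raise ValueError(f"{path}: missing background metadata line")
    return SignalPWM(
        offsets=tuple(offsets),
        cells=np.array(rows),
        background=background,
        pseudocount=float(meta.get("pseudocount", "nan")),
        n_train=int(meta.get("n_train", "0")),
    )
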