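"""Bit-score-weighted matrices of residues around signal cleavage sites.

Given a set of plastid-targeted proteins with consensus cleavage sites, the
residue windows surrounding those sites are stacked and converted into a
per-position bit-score matrix: for each offset ``o`` (anchored at the
cleavage site, with +1 the first mature residue) and residue ``a``,

    cell(o, a) = freq(o, a) * info(o)

where ``info(o)`` is the positional information content in bits,
``log2(20) - H(o)`` with ``H`` the Shannon entropy of the residue
distribution, optionally reduced by the small-sample correction
``e(n) = 19 / (2 ln2 n)``.  These are exactly the letter heights of a
protein sequence logo; trained per species, they drive the transit-peptide
scanner and visualize how strongly the Phe(+1) motif is conserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .cleavage import CleavageSite
from .seqio import AMINO_ACIDS, SequenceRecord

log = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default window: 10 residues of the signal-peptide C-region (offsets
#: -10..0, with 0 the last signal-peptide residue) and the first 15 residues
#: of the transit peptide (+1..+15).
DEFAULT_MATRIX_OFFSETS = range(-10, 16)

MAX_INFO_BITS = math.log2(20)


@dataclass(frozen=True)
class WindowStack:
    """Aligned residue windows around cleavage sites, one row per protein."""

    offsets: tuple[int, ...]
    rows: tuple[str, ...]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a window stack needs at least 2 rows")
        w = len(self.offsets)
        for r in self.rows:
            if len(r) != w:
                raise ValueError("every row must span all offsets")

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class BitScoreMatrix:
    """Per-offset residue frequencies weighted by information content."""

    offsets: tuple[int, ...]
    freq: np.ndarray  # (n_offsets, 20), rows sum to 1
    info: np.ndarray  # (n_offsets,), bits in [0, log2(20)]
    n: int
    pseudocount: float
    correction_applied: bool
    species_tag: str = ""

    def __post_init__(self) -> None:
        if self.freq.shape != (len(self.offsets), 20):
            raise ValueError("freq shape does not match offsets")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1 at every offset")
        if np.any(self.info < 0) or np.any(self.info > MAX_INFO_BITS + 1e-9):
            raise ValueError("information content must lie in [0, log2(20)]")

    @property
    def cells(self) -> np.ndarray:
        """Bit-score weights, ``freq * info`` (letter heights of the logo)."""
        return self.freq * self.info[:, None]

    def cell(self, offset: int, residue: str) -> float:
        """Bit-score weight of ``residue`` at ``offset``; X scores 0."""
        if residue == "X":
            return 0.0
        return float(self.cells[self.offsets.index(offset), _AA_INDEX[residue]])


def build_window_stack(
    sites: Iterable[tuple[SequenceRecord, Union[CleavageSite, int]]],
    offsets: range | Sequence[int] = DEFAULT_MATRIX_OFFSETS,
) -> WindowStack:
    """Stack residue windows around cleavage sites.

    Each item pairs a record with its (consensus) cleavage site or bare
    position.  The residue at offset ``o`` is taken from 1-based sequence
    position ``cleavage + o``, so offset +1 is the first mature residue.
    Records that do not cover the full offset range are skipped with a
    warning and counted in ``n_skipped``.
    """
    offs = tuple(offsets)
    rows: list[str] = []
    skipped = 0
    for record, site in sites:
        pos = site.position if isinstance(site, CleavageSite) else int(site)
        lo, hi = pos + offs[0], pos + offs[-1]
        if lo < 1 or hi > len(record):
            log.warning(
                "record %r (cleavage %d) does not cover offsets %d..%d; skipped",
                record.id, pos, offs[0], offs[-1],
            )
            skipped += 1
            continue
        rows.append("".join(record.residues[pos + o - 1] for o in offs))
    if not rows:
        raise ValueError("all entries were skipped; no usable windows")
    return WindowStack(offsets=offs, rows=tuple(rows), n_skipped=skipped)


def compute_bitscore_matrix(
    stack: WindowStack,
    pseudocount: float = 0.0,
    small_sample_correction: bool = True,
    species_tag: str = "",
) -> BitScoreMatrix:
    """Turn a window stack into a bit-score matrix.

    Per offset ``o``: ``freq(o, a) = (count + pc) / (n_eff + 20 pc)`` with
    ``n_eff`` the non-X count at that column; ``info(o) = log2(20) - H(o) -
    e`` with ``e = 19 / (2 ln2 n_eff)`` when the correction is on, clamped
    at 0 from below.  An all-X column is an error.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    offs = stack.offsets
    counts = np.zeros((len(offs), 20))
    n_eff = np.zeros(len(offs))
    for row in stack.rows:
        for i, residue in enumerate(row):
            if residue != "X":
                counts[i, _AA_INDEX[residue]] += 1
                n_eff[i] += 1
    for i, o in enumerate(offs):
        if n_eff[i] == 0:
            raise ValueError(f"offset {o}: every training residue is X")
    freq = (counts + pseudocount) / (n_eff[:, None] + 20 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    correction = (
        (20 - 1) / (2 * math.log(2) * n_eff) if small_sample_correction else 0.0
    )
    info = np.maximum(0.0, MAX_INFO_BITS - entropy - correction)
    return BitScoreMatrix(
        offsets=offs,
        freq=freq,
        info=info,
        n=stack.n,
        pseudocount=pseudocount,
        correction_applied=small_sample_correction,
        species_tag=species_tag,
    )


# --- TSV serialization -----------------------------------------------------

def write_matrix(matrix: BitScoreMatrix, path: str | Path) -> None:
    """Serialize as TSV: rows = offsets, 20 residue columns of bit-score
    weights, plus ``freq_sum`` and ``info`` columns, '#' metadata header."""
    cells = matrix.cells
    with open(path, "w") as fh:
        fh.write(f"# n\t{matrix.n}\n")
        fh.write(f"# pseudocount\t{matrix.pseudocount!r}\n")
        fh.write(f"# correction\t{'on' if matrix.correction_applied else 'off'}\n")
        fh.write(f"# species_tag\t{matrix.species_tag}\n")
        fh.write("offset\t" + "\t".join(AMINO_ACIDS) + "\tfreq_sum\tinfo\n")
        for i, o in enumerate(matrix.offsets):
            fh.write(
                str(o)
                + "\t"
                + "\t".join(repr(float(c)) for c in cells[i])
                + f"\t{float(matrix.freq[i].sum())!r}\t{float(matrix.info[i])!r}\n"
            )
        # frequencies appended as comments so the matrix round-trips even
        # where info == 0 (cells alone cannot recover freq there)
        for i, o in enumerate(matrix.offsets):
            fh.write(
                f"#freq\t{o}\t" + "\t".join(repr(float(f)) for f in matrix.freq[i]) + "\n"
            )


def read_matrix(path: str | Path) -> BitScoreMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    meta: dict[str, str] = {}
    offsets: list[int] = []
    infos: list[float] = []
    freq_rows: dict[int, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#freq\t"):
                parts = line.split("\t")
                freq_rows[int(parts[1])] = [float(x) for x in parts[2:]]
            elif line.startswith("#"):
                parts = line[1:].strip().split("\t")
                meta[parts[0]] = parts[1] if len(parts) > 1 else ""
            elif line.startswith("offset"):
                continue
            else:
                parts = line.split("\t")
                offsets.append(int(parts[0]))
                infos.append(float(parts[-1]))
    freq = np.array([freq_rows[o] for o in offsets])
    return BitScoreMatrix(
        offsets=tuple(offsets),
        freq=freq,
        info=np.array(infos),
        n=int(meta.get("n", "0")),
        pseudocount=float(meta.get("pseudocount", "0")),
        correction_applied=meta.get("correction", "on") == "on",
        species_tag=meta.get("species_tag", ""),
    )


# --- sequence-logo rendering ----------------------------------------------

_LOGO_COLORS = {
    # fixed default scheme: chemistry classes
    **{a: "#2c7fb8" for a in "AVLIMFW"},   # hydrophobic
    **{a: "#31a354" for a in "STNQYCG"},   # polar/small
    **{a: "#e6550d" for a in "KRH"},       # basic
    **{a: "#c51b8a" for a in "DE"},        # acidic
    "P": "#636363",
}


def export_logo(
    matrix: BitScoreMatrix,
    path: str | Path,
    mode: str = "bits",
    title: Optional[str] = None,
) -> None:
    """Render the matrix as a sequence logo (SVG or PNG by extension).

    In ``bits`` mode the stack height at each offset equals ``info(o)`` and
    letter heights equal the bit-score weights ``cell(o, a)``; in
    ``frequency`` mode letters are stacked to total height 1.  Letters are
    drawn smallest-to-largest bottom-up; the cleavage boundary is marked
    between the last signal-peptide column and the first mature column (+1).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if mode not in {"bits", "frequency"}:
        raise ValueError(f"mode must be 'bits' or 'frequency', got {mode!r}")
    heights = matrix.cells if mode == "bits" else matrix.freq
    ymax = MAX_INFO_BITS if mode == "bits" else 1.0

    fig, ax = plt.subplots(figsize=(max(6.0, 0.38 * len(matrix.offsets)), 2.8))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for i, o in enumerate(matrix.offsets):
        y = 0.0
        order = np.argsort(heights[i])  # ascending: tallest letter on top
        for j in order:
            h = float(heights[i, j])
            if h <= 1e-9:
                continue
            letter = AMINO_ACIDS[j]
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            sx = 0.9 / bbox.width
            sy = h / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(sx, sy)
                .translate(i + 0.05, y)
            )
            ax.add_patch(
                PathPatch(
                    tp.transformed(transform),
                    facecolor=_LOGO_COLORS.get(letter, "black"),
                    edgecolor="none",
                )
            )
            y += h
    # cleavage bond sits between offset <= 0 (signal) and +1 (mature)
    if 1 in matrix.offsets:
        ax.axvline(matrix.offsets.index(1), color="black", linestyle="--", lw=0.8)
    ax.set_xlim(-0.5, len(matrix.offsets))
    ax.set_ylim(0, ymax)
    ax.set_xticks(range(len(matrix.offsets)))
    ax.set_xticklabels([f"{o:+d}" if o > 0 else str(o) for o in matrix.offsets],
                       fontsize=7, rotation=90)
    ax.set_ylabel("bits" if mode == "bits" else "frequency")
    ax.set_xlabel("position relative to cleavage site")
    if title or matrix.species_tag:
        ax.set_title(title or matrix.species_tag, fontsize=9)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
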