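"""Sequence and reference-table I/O, plus N-terminus curation.

Proteins routed to complex (secondary) plastids carry a bipartite targeting
signal (BTS) at their very N-terminus, so every downstream step of this
package — cleavage-site prediction, matrix training, window scanning — is
only meaningful on sequences whose N-termini are complete.  This module
provides the FASTA plumbing, the labelled reference tables used for training
and benchmarking, and a transcript-overlap extension step that repairs
5'-truncated gene models by borrowing upstream residues from an overlapping
transcript of the same gene.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted everywhere: the 20 standard letters plus X.
#: X marks any ambiguous/non-standard character and never contributes to
#: matrix training or scoring.
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: Closed set of compartment labels used in reference tables.
COMPARTMENTS = frozenset({"plastid", "mitochondrion", "cytosol", "secretory"})


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    residues : str
        Uppercase residues over the 21-letter alphabet (20 standard + X).
    description : str
        Free-text description (FASTA header text after the id).
    chimeric : bool
        True when the N-terminus was extended from another source sequence.
    source : str
        Free-text provenance tag.
    """

    id: str
    residues: str
    description: str = ""
    chimeric: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside the "
                f"21-letter alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceEntry:
    """A curated reference protein with its compartment label.

    ``known_cleavage`` is the 1-based index of the *last* residue of the
    signal peptide; the mature protein starts at ``known_cleavage + 1``
    (the "+1" convention used throughout the package).
    """

    record: SequenceRecord
    label: str
    known_cleavage: Optional[int] = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.label not in COMPARTMENTS:
            raise ValueError(
                f"entry {self.record.id!r}: label {self.label!r} not in "
                f"{sorted(COMPARTMENTS)}"
            )
        if self.known_cleavage is not None:
            if not (1 <= self.known_cleavage < len(self.record)):
                raise ValueError(
                    f"entry {self.record.id!r}: known_cleavage "
                    f"{self.known_cleavage} outside [1, {len(self.record) - 1}]"
                )


def _sanitize(raw: str, rec_id: str) -> str:
    residues = raw.upper()
    bad = sorted(set(residues) - ALPHABET)
    if bad:
        log.warning(
            "record %r: replaced %d non-standard character(s) %s with X",
            rec_id,
            sum(residues.count(c) for c in bad),
            bad,
        )
        table = str.maketrans({c: "X" for c in bad})
        residues = residues.translate(table)
    return residues


def read_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased; characters outside the 21-letter alphabet are
    replaced by X with a logged warning.  Order is preserved.  Duplicate ids,
    empty sequences and empty files are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = str(bio.seq)
        if not residues:
            raise ValueError(f"FASTA entry {bio.description!r} has an empty sequence")
        if bio.id in seen:
            raise ValueError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description
        if desc == bio.id:
            desc = ""
        elif desc.startswith(bio.id + " "):
            desc = desc[len(bio.id) + 1 :]
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=_sanitize(residues, bio.id),
                description=desc,
                source=source or str(path),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-line FASTA (60-column wrap).

    Round-trips exactly through :func:`read_fasta` on id, description and
    residues.
    """
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")


def extend_n_terminus(
    target: SequenceRecord,
    candidates: Iterable[SequenceRecord],
    min_overlap: int = 30,
) -> SequenceRecord:
    """Extend a (possibly 5'-truncated) protein using overlapping candidates.

    If the first ``min_overlap`` residues of ``target`` occur as an exact
    substring of a candidate at a position preceded by at least one residue,
    the candidate's upstream residues are prepended and the result is flagged
    ``chimeric``.  Among qualifying candidates the longest extension wins;
    ties break on candidate id (lexicographic).  Otherwise the target is
    returned unchanged with ``chimeric=False``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(target) < min_overlap:
        raise ValueError(
            f"target {target.id!r} is shorter ({len(target)}) than "
            f"min_overlap ({min_overlap})"
        )
    prefix = target.residues[:min_overlap]
    best: Optional[tuple[int, str, str]] = None  # (ext_len, cand_id, extension)
    for cand in candidates:
        # rightmost occurrence gives the longest upstream extension
        pos = cand.residues.rfind(prefix)
        if pos >= 1:
            key = (pos, cand.id)
            if best is None or pos > best[0] or (pos == best[0] and cand.id < best[1]):
                best = (pos, cand.id, cand.residues[:pos])
    if best is None:
        return replace(target, chimeric=False)
    ext_len, cand_id, extension = best
    log.info(
        "extended %r by %d residue(s) from candidate %r", target.id, ext_len, cand_id
    )
    return replace(
        target,
        residues=extension + target.residues,
        chimeric=True,
        source=(target.source + f" +5'ext:{cand_id}").strip(),
    )


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "yes", "y"}


def read_reference_table(
    path: str | Path,
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
) -> list[ReferenceEntry]:
    """Read a labelled reference table (TSV) against a sequence collection.

    Expected header columns: ``id``, ``label``; optional ``known_cleavage``,
    ``excluded`` (truthy flag), ``exclusion_reason``.  Every id must resolve
    in ``sequences``; unknown labels and malformed rows are hard errors.
    """
    if not isinstance(sequences, Mapping):
        by_id: dict[str, SequenceRecord] = {}
        for rec in sequences:
            if rec.id in by_id:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            by_id[rec.id] = rec
        sequences = by_id
    path = Path(path)
    entries: list[ReferenceEntry] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with an 'id' column")
        if "label" not in reader.fieldnames:
            raise ValueError(f"{path}: missing 'label' column")
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("id") or "").strip()
            label = (row.get("label") or "").strip()
            if not rid or not label:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            if rid not in sequences:
                raise KeyError(
                    f"{path}:{lineno}: id {rid!r} not found in the sequence collection"
                )
            cleav_text = (row.get("known_cleavage") or "").strip()
            known_cleavage: Optional[int] = None
            if cleav_text:
                try:
                    known_cleavage = int(cleav_text)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: known_cleavage {cleav_text!r} is not "
                        "an integer"
                    ) from exc
                if known_cleavage < 1:
                    raise ValueError(
                        f"{path}:{lineno}: known_cleavage must be positive"
                    )
            try:
                entries.append(
                    ReferenceEntry(
                        record=sequences[rid],
                        label=label,
                        known_cleavage=known_cleavage,
                        excluded=_parse_bool(row.get("excluded") or ""),
                        exclusion_reason=(row.get("exclusion_reason") or "").strip(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return entries


def write_reference_table(entries: Iterable[ReferenceEntry], path: str | Path) -> None:
    """Write reference entries as a TSV readable by :func:`read_reference_table`."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label", "known_cleavage", "excluded", "exclusion_reason"])
        for e in entries:
            writer.writerow(
                [
                    e.record.id,
                    e.label,
                    "" if e.known_cleavage is None else e.known_cleavage,
                    "true" if e.excluded else "",
                    e.exclusion_reason,
                ]
            )
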