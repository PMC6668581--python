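"""Seeded generator of labelled protein fixtures with BTS-like presequences.

Real chromerid reference sets cannot be bundled, so this module fabricates
proteomes with exactly the N-terminal architecture the prediction pipeline
assumes:

* **plastid** — Met, a short charged/neutral n-region, a hydrophobic
  h-region, a polar c-region with the Ala-X-Ala peptidase motif, then a
  transit peptide whose first residue (+1) is Phe with a profile-dependent
  probability (strong for the *Chromera*-like profile, weaker for the
  *Vitrella*-like one) and which is enriched in Ser/Thr/Arg, padding the
  N-terminal extension to 40-80 residues before a background mature domain;
* **secretory** — the same signal peptide, but a background mature protein
  immediately after cleavage (no transit peptide);
* **mitochondrion** — a shorter Arg-rich presequence devoid of acidic
  residues;
* **cytosol** — Met plus background residues only.

Everything is drawn from a single seeded generator, so a fixture is fully
reproducible, and the truth table records each class and exact cleavage
position for the signal-bearing classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    ReferenceEntry,
    SequenceRecord,
    write_fasta,
    write_reference_table,
)

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

PROFILES = ("cvelia_like", "vbrassicaformis_like")

#: Phe(+1) conservation per species profile: strongly conserved in the
#: Chromera-like profile, about half of proteins in the Vitrella-like one.
DEFAULT_PHE_PROB = {"cvelia_like": 0.8, "vbrassicaformis_like": 0.5}

N_REGION_RESIDUES = "KRNQSTGA"          # charged/neutral
H_REGION_RESIDUES = "ALIVFWM"           # hydrophobic core
C_REGION_RESIDUES = "ASGTQN"            # small/polar

#: Combined Ser/Thr/Arg frequency in the synthetic transit peptide.
TRANSIT_STR_FREQ = 0.45


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Lengths are in residues.  ``signal_len_range`` is the signal-peptide
    length; ``bts_extension_range`` the total presequence (signal + transit)
    of plastid proteins; ``mito_presequence_range`` the mitochondrial
    presequence.  ``background`` is a 20-vector of residue frequencies
    (uniform by default).
    """

    n_per_class: int = 200
    seed: int = 0
    species_profile: str = "cvelia_like"
    phe_plus1_prob: Optional[float] = None  # None -> profile default
    signal_len_range: range = range(16, 29)
    bts_extension_range: range = range(40, 81)
    mito_presequence_range: range = range(15, 41)
    mature_len_range: range = range(150, 401)
    background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.species_profile not in PROFILES:
            raise ValueError(f"species_profile must be one of {PROFILES}")
        p = self.phe_prob
        if not (0.0 <= p <= 1.0):
            raise ValueError("phe_plus1_prob must lie in [0, 1]")
        for r in (self.signal_len_range, self.bts_extension_range,
                  self.mito_presequence_range, self.mature_len_range):
            if len(r) == 0:
                raise ValueError("length ranges must be non-empty")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9:
                raise ValueError("background must be 20 frequencies summing to 1")

    @property
    def phe_prob(self) -> float:
        if self.phe_plus1_prob is not None:
            return self.phe_plus1_prob
        return DEFAULT_PHE_PROB[self.species_profile]

    @property
    def bg(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 0.05)
        return np.asarray(self.background, dtype=float)


def _transit_probs(bg: np.ndarray) -> np.ndarray:
    """Transit-peptide residue distribution: S/T/R jointly at
    ``TRANSIT_STR_FREQ``, the rest proportional to the background."""
    probs = bg.copy()
    str_idx = [_AA_INDEX[a] for a in "STR"]
    mask = np.ones(20, dtype=bool)
    mask[str_idx] = False
    probs[str_idx] = TRANSIT_STR_FREQ / 3
    probs[mask] *= (1 - TRANSIT_STR_FREQ) / probs[mask].sum()
    return probs


def _sample(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    if n <= 0:
        return ""
    return "".join(_AA[rng.choice(20, size=n, p=probs)])


def _uniform_over(rng: np.random.Generator, n: int, letters: str) -> str:
    if n <= 0:
        return ""
    pool = np.array(list(letters))
    return "".join(pool[rng.integers(0, len(pool), size=n)])


def _signal_peptide(rng: np.random.Generator, spec: FixtureSpec) -> str:
    """Tripartite signal peptide: Met + n-region (1-5) + h-region (7-13) +
    polar c-region ending in the Ala-X-Ala peptidase motif."""
    length = int(rng.choice(np.array(spec.signal_len_range)))
    n_len = int(rng.integers(1, min(5, max(1, length - 1 - 7 - 3)) + 1))
    h_max = min(13, length - 1 - n_len - 3)
    h_len = int(rng.integers(7, h_max + 1)) if h_max > 7 else max(1, h_max)
    c_len = length - 1 - n_len - h_len
    c = list(_uniform_over(rng, c_len, C_REGION_RESIDUES))
    # peptidase recognition: Ala at -3 and -1 relative to the cleavage bond
    if c_len >= 1:
        c[-1] = "A"
    if c_len >= 3:
        c[-3] = "A"
    sp = "M" + _uniform_over(rng, n_len, N_REGION_RESIDUES) \
         + _uniform_over(rng, h_len, H_REGION_RESIDUES) + "".join(c)
    assert len(sp) == length
    return sp


def _mito_probs(bg: np.ndarray) -> np.ndarray:
    """Mitochondrial presequence distribution: Arg at 0.25, no Asp/Glu."""
    probs = bg.copy()
    probs[[_AA_INDEX["D"], _AA_INDEX["E"]]] = 0.0
    r = _AA_INDEX["R"]
    probs[r] = 0.0
    probs *= 0.75 / probs.sum()
    probs[r] = 0.25
    return probs


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], list[ReferenceEntry]]:
    """Generate a labelled fixture: FASTA-ready records plus truth entries.

    Deterministic for a given spec (byte-identical output, same seed).
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.bg
    transit_probs = _transit_probs(bg)
    mito_probs = _mito_probs(bg)
    f_idx = _AA_INDEX["F"]
    transit_no_f = transit_probs.copy()
    transit_no_f[f_idx] = 0.0
    transit_no_f /= transit_no_f.sum()

    records: list[SequenceRecord] = []
    entries: list[ReferenceEntry] = []
    prefix = spec.species_profile

    def add(label: str, i: int, residues: str, cleavage: Optional[int]) -> None:
        rec = SequenceRecord(
            id=f"{prefix}_{label}_{i:04d}",
            residues=residues,
            description=f"synthetic {label} protein ({prefix})",
            source="synthetic",
        )
        records.append(rec)
        entries.append(
            ReferenceEntry(record=rec, label=label, known_cleavage=cleavage)
        )

    for i in range(spec.n_per_class):
        # plastid: signal peptide + Phe(+1)-anchored S/T/R-rich transit
        sp = _signal_peptide(rng, spec)
        ext = int(rng.choice(np.array(spec.bts_extension_range)))
        transit_len = max(1, ext - len(sp))
        if rng.random() < spec.phe_prob:
            first = "F"
        else:
            first = _sample(rng, 1, transit_no_f)
        transit = first + _sample(rng, transit_len - 1, transit_probs)
        mature = _sample(rng, int(rng.choice(np.array(spec.mature_len_range))), bg)
        add("plastid", i, sp + transit + mature, len(sp))

    for i in range(spec.n_per_class):
        # secretory: same signal peptide, background mature domain
        sp = _signal_peptide(rng, spec)
        mature = _sample(rng, int(rng.choice(np.array(spec.mature_len_range))), bg)
        add("secretory", i, sp + mature, len(sp))

    for i in range(spec.n_per_class):
        # mitochondrion: shorter Arg-rich presequence, no D/E
        pre_len = int(rng.choice(np.array(spec.mito_presequence_range)))
        pre = "M" + _sample(rng, pre_len - 1, mito_probs)
        mature = _sample(rng, int(rng.choice(np.array(spec.mature_len_range))), bg)
        add("mitochondrion", i, pre + mature, None)

    for i in range(spec.n_per_class):
        # cytosol: no presequence at all
        body = _sample(rng, int(rng.choice(np.array(spec.mature_len_range))), bg)
        add("cytosol", i, "M" + body, None)

    return records, entries


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Generate a fixture and write ``proteins.faa`` + ``truth.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, entries = generate_fixture(spec)
    fasta = out_dir / "proteins.faa"
    truth = out_dir / "truth.tsv"
    write_fasta(records, fasta)
    write_reference_table(entries, truth)
    return fasta, truth
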