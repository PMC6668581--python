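# Methods

## Coordinate convention

Throughout the package a cleavage site is the 1-based index of the **last
residue of the signal peptide**; the mature protein starts at the next
residue, labelled **+1**. Offsets are plain arithmetic: the residue at
offset *o* of a window anchored at cleavage position *c* is sequence
position *c + o*, so offset 0 is the last signal-peptide residue and +1 the
first transit-peptide residue. The logo's cleavage marker is drawn between
the 0 and +1 columns.

## Cleavage-site PWM

The built-in predictor is a position-weight matrix over offsets −13…+2
(the classic signal-peptidase footprint; configurable). Cells are

    cell(o, a) = log2( (n_a(o) + q) / (n(o) + 20 q) / b(a) )

with pseudocount *q* (default 1; must be positive so all cells stay
finite), per-column non-X counts *n(o)*, and background *b* (uniform 0.05
by default; a background estimated from user-supplied sequences is
available via `background_from_records`). Candidate positions 10…45 are
scanned (signal peptides of BTS proteins end well inside this range;
positions below 10 cannot hold a complete signal peptide); the
maximal-score position is returned if it reaches `min_score` (default 0),
ties to the smallest position. X residues contribute 0 everywhere. The
scan is exactly equivalent to the brute-force enumeration of all candidate
positions; a property test asserts this on random instances.

## Consensus calling

Multiple predictors' sites for one protein are combined by **strict
majority of the predictors that reported any site**, requiring exact
positional identity by default. The majority rule and the positional
tolerance (`tolerance=1` lets ±1 count as agreement) are exposed because
published descriptions of "majority agreement" rarely pin down either; the
defaults take the strict reading. The consensus site carries the number of
supporting predictors as its score.

## Bit-score matrix

Training windows span offsets −10…+15 by default: enough of the
signal-peptide C-region to capture the cleavage motif and the first 15
transit-peptide residues where Phe(+1) and the Ser/Thr/Arg enrichment
live. Frequencies use a per-column effective count that excludes X, so
partially ambiguous reference sequences still contribute their unambiguous
columns rather than being dropped. Information content uses the
small-sample correction *e(n) = 19/(2·ln2·n)* (Schneider convention, the
same one sequence-logo tools apply); it is ON for real training and OFF in
unit tests with analytic expectations. Negative post-correction
information is clamped to 0 — bit scores feed a cumulative scorer that
must never reward the absence of signal. Matrices serialize as TSV with
the bit-score cells, per-row `freq_sum` and `info` columns, and the raw
frequencies appended as `#freq` comment lines so a matrix round-trips even
where `info = 0`.

## Window scanner and decision cascade

The cumulative score sums the matrix over its full span anchored at the
cleavage site (out-of-sequence offsets and X contribute 0). Published
descriptions of the original ASAFind score do not fix whether it sums a
fixed span or the best window only; the full-span definition used here is
documented so results are self-consistent even if numerically different
from that tool, and the window agreement is kept as a separate boolean. A
5-residue window slides over shifts −5…+5 of the transit-peptide start;
the best shift (ties to smallest |shift|, then smallest shift) must lie
within ±2 of the site for the scan to "agree" — the Phe motif occupies +1
and the scan must localize it at, not merely near, the cleavage site.
Decision cascade: no site → mitochondrion (external score ≥ its threshold)
or other; site + cumulative ≥ threshold + agreement → plastid; site
otherwise → secretory. Scan failures on valid records degrade to "other"
with a warning, never a crash. Shipped presets carry the chromerid
cumulative-score thresholds (1.4 Chromera-type, 1.0 Vitrella-type);
mitochondrial calling is delegated to external predictor scores — no
internal mitochondrial model is trained.

## Benchmarking

Score ≥ threshold counts as a positive call (the inclusive convention).
Sensitivity and precision with empty denominators return `None`, never 0
or 1, so undefined points cannot silently inflate a curve. Threshold
sweeps default to the sorted unique scores (every achievable operating
point exactly once); sensitivity is then weakly decreasing by counting.
The dual-threshold report selects, per predictor: the **largest** threshold
with sensitivity ≥ the sensitivity floor (this maximizes precision subject
to the floor, a deterministic rule chosen because "aimed at higher
sensitivity" does not define one), and the **smallest** threshold with
precision ≥ the precision floor (maximizing sensitivity subject to it).
Unattainable floors return the closest point flagged `attainable=False`.
Multi-class evaluation is one-vs-rest per positive class.

## Synthetic fixtures

The generator emulates the four compartment classes the method
distinguishes, with the presequence architecture the predictors assume:

- **plastid**: Met + 1–5 charged/neutral n-region residues + 7–13
  hydrophobic h-region residues + a polar c-region ending in Ala-X-Ala;
  signal length drawn from 16–28; the transit peptide starts with Phe with
  probability 0.8 (Chromera-like profile) or 0.5 (Vitrella-like) and is
  enriched in Ser/Thr/Arg (combined frequency 0.45), padding the total
  N-terminal extension to 40–80 residues; mature domain 150–400
  background residues.
- **secretory**: the same signal peptide, background mature domain.
- **mitochondrion**: Met + a 15–40-residue presequence with Arg at 0.25
  and no Asp/Glu.
- **cytosol**: Met + background only.

The tripartite n/h/c signal composition and the Ala-X-Ala motif follow the
textbook description of signal peptides; the S/T/R enrichment level is a
parameter motivated by the general hydroxylated-residue enrichment of
chloroplast transit peptides, not a measured chromerid value. The
background is uniform (0.05 per residue) so analytic expectations in tests
are exact. What passing tests show is that the pipeline recovers planted
structure under this idealized model; real proteomes add homology
redundancy, compositional bias, signal anchors and dual-targeted proteins,
none of which the generator emulates, so measured sensitivities and
precisions on real data will differ.

## Problem sizes and seeds

Training sets of 200 proteins per class and held-out sets of 100 per class
are the package's standard demonstration scale; they keep every analysis
comfortably within interactive runtimes while leaving binomial sampling
bands (±0.06 at n=200) tight enough for the composition and contrast
properties to be meaningful. All stochastic steps draw from
`numpy.random.default_rng` seeded explicitly; fixtures are byte-identical
across runs for a fixed spec.

## Known limitations

- The cumulative score's scale depends on the matrix span, so thresholds
  are only comparable between matrices trained with the same offsets; the
  shipped 1.4/1.0 presets apply to ASAFind-style scores and need
  re-calibration (`calibrate_threshold`) for matrices trained here.
- The Vitrella-like profile's weaker Phe(+1) conservation genuinely limits
  achievable sensitivity at fixed precision — the species contrast, not an
  implementation artifact.
- No signal-anchor (type II) discrimination, no dual-targeting calls, no
  redundancy weighting of training sequences.
- Per-tool adapter dialects are best-effort column maps; only the
  documented `generic` TSV dialect is guaranteed.
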