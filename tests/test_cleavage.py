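"""Cleavage-site PWM training/prediction and consensus calling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from btspred.cleavage import (
    CleavageSite,
    SignalPWM,
    consensus_cleavage,
    predict_cleavage_pwm,
    score_position,
    train_signal_pwm,
    uniform_background,
)
from btspred.seqio import AMINO_ACIDS, ReferenceEntry, SequenceRecord

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def entry(residues, cleavage, label="plastid", rid="r"):
    return ReferenceEntry(
        record=SequenceRecord(id=rid, residues=residues),
        label=label,
        known_cleavage=cleavage,
    )


def zero_pwm(offsets=range(-2, 2)):
    offs = tuple(offsets)
    return SignalPWM(
        offsets=offs,
        cells=np.zeros((len(offs), 20)),
        background=uniform_background(),
        pseudocount=1.0,
        n_train=0,
    )


class TestTrainSignalPWM:
    def test_identical_windows_tiny_pseudocount_approaches_log_odds_limit(self):
        # every training window reads "AL" at offsets 0..1; as pc -> 0 the
        # observed residue's cell tends to log2(1/0.05) = log2 20
        entries = [
            entry("MKKKKALWWWW", 6, rid=f"e{i}") for i in range(4)
        ]
        pwm = train_signal_pwm(entries, offsets=range(0, 2), pseudocount=1e-9)
        assert pwm.cell(0, "A") == pytest.approx(math.log2(20), abs=1e-6)
        assert pwm.cell(1, "L") == pytest.approx(math.log2(20), abs=1e-6)
        # unseen residues are large-negative but finite (pseudocount bounded)
        assert pwm.cell(0, "W") < -20 and math.isfinite(pwm.cell(0, "W"))

    def test_training_frequencies_equal_to_background_give_zero_cells(self):
        # 20 windows, one per residue, uniform background 0.05, pc -> 0
        entries = [
            entry("M" * 5 + a + "W" * 5, 6, rid=f"e_{a}") for a in AMINO_ACIDS
        ]
        pwm = train_signal_pwm(entries, offsets=range(0, 1), pseudocount=1e-12)
        assert np.allclose(pwm.cells, 0.0, atol=1e-6)

    def test_four_toy_windows_match_counting_oracle(self):
        windows = ["AC", "AD", "AC", "LC"]
        entries = [entry("MKKKK" + w + "WWWW", 6, rid=f"e{i}")
                   for i, w in enumerate(windows)]
        pwm = train_signal_pwm(entries, offsets=range(0, 2), pseudocount=1.0)
        # independent brute-force count oracle
        for o in (0, 1):
            counts = {a: sum(1 for w in windows if w[o] == a) for a in AMINO_ACIDS}
            for a in AMINO_ACIDS:
                expected = math.log2(((counts[a] + 1.0) / (4 + 20.0)) / 0.05)
                assert pwm.cell(o, a) == pytest.approx(expected, abs=1e-12)

    def test_short_entries_skipped_and_too_few_usable_errors(self):
        good = entry("MKKKKALWWWW", 6, rid="ok")
        short = entry("MAL", 2, rid="short")  # cannot cover -13..+2
        with pytest.raises(ValueError, match="usable"):
            train_signal_pwm([good, short])

    def test_x_residues_never_counted(self):
        entries = [entry("MKKKK" + w + "WWWW", 6, rid=f"e{i}")
                   for i, w in enumerate(["AC", "XC", "AC", "XC"])]
        pwm = train_signal_pwm(entries, offsets=range(0, 2), pseudocount=1.0)
        # offset 0 saw only 2 non-X residues, both A
        assert pwm.cell(0, "A") == pytest.approx(
            math.log2(((2 + 1) / (2 + 20)) / 0.05), abs=1e-12
        )


class TestPredictCleavagePWM:
    def test_all_zero_pwm_ties_break_to_first_position(self):
        rec = SequenceRecord(id="r", residues="M" * 60)
        site = predict_cleavage_pwm(rec, zero_pwm(), min_score=0.0)
        assert site is not None and site.position == 10

    def test_infinite_min_score_gives_absent(self):
        rec = SequenceRecord(id="r", residues="M" * 60)
        assert predict_cleavage_pwm(rec, zero_pwm(), min_score=math.inf) is None

    def test_short_sequence_restricts_range_and_may_be_absent(self):
        rec = SequenceRecord(id="r", residues="MKL")
        assert predict_cleavage_pwm(rec, zero_pwm()) is None

    def test_planted_motif_is_found_and_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(41)
        aas = np.array(list(AMINO_ACIDS))
        for trial in range(25):
            # random PWM, random record: prediction must equal a brute scan
            offs = range(-3, 3)
            cells = rng.normal(size=(len(offs), 20))
            pwm = SignalPWM(offsets=tuple(offs), cells=cells,
                            background=uniform_background(),
                            pseudocount=1.0, n_train=10)
            rec = SequenceRecord(
                id=f"r{trial}", residues="".join(rng.choice(aas, size=80))
            )
            got = predict_cleavage_pwm(rec, pwm, min_score=-math.inf)
            # oracle: exhaustive scan, first max
            best_p, best_s = None, -math.inf
            for p in range(10, 46):
                if p - 3 < 1 or p + 2 > 80:
                    continue
                s = sum(
                    cells[i, AA_INDEX[rec.residues[p + o - 1]]]
                    for i, o in enumerate(offs)
                )
                if s > best_s:
                    best_p, best_s = p, s
            assert got.position == best_p
            assert got.score == pytest.approx(best_s, abs=1e-9)

    def test_training_recovery_on_strong_motif_fixture(self, cvelia_fixture,
                                                       cvelia_models):
        # predicting on the training entries themselves recovers the known
        # cleavage site for at least 90% of signal-bearing proteins
        _, entries = cvelia_fixture
        usable = [e for e in entries if e.known_cleavage is not None]
        hits = sum(
            1
            for e in usable
            if (s := predict_cleavage_pwm(e.record, cvelia_models.pwm))
            and s.position == e.known_cleavage
        )
        assert hits / len(usable) >= 0.90


def site(pos, predictor, rid="r", score=1.0):
    return CleavageSite(record_id=rid, position=pos, predictor=predictor,
                        score=score)


class TestConsensus:
    def test_unanimity(self):
        sites = [site(24, p) for p in "abcd"]
        out = consensus_cleavage(sites)
        assert out.position == 24 and out.score == 4 and out.predictor == "consensus"

    def test_two_of_four_is_not_a_strict_majority(self):
        sites = [site(24, "a"), site(24, "b"), site(31, "c"), site(33, "d")]
        assert consensus_cleavage(sites) is None

    def test_absent_predictors_shrink_the_electorate(self):
        sites = [site(24, "a"), site(24, "b"), site(24, "c"), None]
        out = consensus_cleavage(sites)
        assert out.position == 24 and out.score == 3

    def test_same_predictor_twice_is_error(self):
        with pytest.raises(ValueError, match="same predictor"):
            consensus_cleavage([site(24, "a"), site(25, "a")])

    def test_positional_tolerance_counts_near_agreement(self):
        sites = [site(24, "a"), site(25, "b"), site(40, "c")]
        assert consensus_cleavage(sites) is None           # strict default
        out = consensus_cleavage(sites, tolerance=1)
        assert out is not None and out.position in (24, 25)

    @given(
        positions=st.lists(
            st.one_of(st.none(), st.integers(min_value=10, max_value=40)),
            min_size=1,
            max_size=6,
        ),
        seed=st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, positions, seed):
        sites = [
            None if p is None else site(p, predictor=f"pred{i}")
            for i, p in enumerate(positions)
        ]
        shuffled = list(sites)
        seed.shuffle(shuffled)
        a, b = consensus_cleavage(sites), consensus_cleavage(shuffled)
        if a is None:
            assert b is None
        else:
            assert b is not None and (a.position, a.score) == (b.position, b.score)
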