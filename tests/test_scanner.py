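"""Shuffling, PWM scanning against a brute-force oracle, and empirical
threshold calibration."""

import math
from collections import Counter

import numpy as np
import pytest

from crmscan.motif_io import UNIFORM_BACKGROUND, build_pwm
from crmscan.scanner import (Hit, SequenceRecord, calibrate_threshold,
                             compute_occurrence_frequency, count_hits_in_set,
                             reverse_complement, scan_sequence, shuffle_set,
                             window_scores)
from crmscan.synthetic import ebox_anchor_matrix, random_site_matrix

ANCHOR = ebox_anchor_matrix()
ANCHOR_PWM = build_pwm(ANCHOR)
CONSENSUS = "GACACCTGTC"


def random_records(rng, n, length, alphabet="ACGT"):
    return [SequenceRecord(f"s{i}", "".join(rng.choice(list(alphabet), length)), 0)
            for i in range(n)]


def brute_force_hits(rec, pwm, threshold):
    """Rescore every window on both strands with plain Python loops."""
    idx = {b: i for i, b in enumerate("ACGT")}
    hits = []
    m = pwm.length
    for s in range(len(rec.sequence) - m + 1):
        window = rec.sequence[s:s + m]
        if "N" in window:
            continue
        fwd = sum(pwm.weights[i, idx[window[i]]] for i in range(m))
        if fwd >= threshold:
            hits.append((rec.seq_id, s, "+", round(fwd, 9)))
        rc = reverse_complement(window)
        rev = sum(pwm.weights[i, idx[rc[i]]] for i in range(m))
        if rev >= threshold:
            hits.append((rec.seq_id, s, "-", round(rev, 9)))
    return sorted(hits)


class TestShuffle:
    def test_preserves_composition_count_and_lengths(self):
        rng = np.random.default_rng(0)
        records = random_records(rng, 20, 150, alphabet="ACGTN")
        shuffled = shuffle_set(records, seed=1)
        assert len(shuffled) == len(records)
        for orig, shuf in zip(records, shuffled):
            assert len(shuf.sequence) == len(orig.sequence)
            assert Counter(shuf.sequence) == Counter(orig.sequence)
            assert shuf.seq_id == orig.seq_id

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        records = random_records(rng, 10, 100)
        a = [r.sequence for r in shuffle_set(records, seed=7)]
        b = [r.sequence for r in shuffle_set(records, seed=7)]
        c = [r.sequence for r in shuffle_set(records, seed=8)]
        assert a == b
        assert a != c

    def test_dinucleotide_mode_preserves_dimer_counts(self):
        rng = np.random.default_rng(2)
        records = random_records(rng, 5, 200)
        shuffled = shuffle_set(records, seed=3, k=2)
        for orig, shuf in zip(records, shuffled):
            dimers = lambda s: Counter(s[i:i + 2] for i in range(len(s) - 1))
            assert dimers(shuf.sequence) == dimers(orig.sequence)
            assert shuf.sequence[0] == orig.sequence[0]
            assert shuf.sequence[-1] == orig.sequence[-1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shuffle_set([], seed=0)


class TestScan:
    def test_unattainable_threshold_gives_no_hits(self):
        rng = np.random.default_rng(4)
        rec = random_records(rng, 1, 200)[0]
        assert scan_sequence(rec, ANCHOR_PWM, ANCHOR_PWM.max_score + 1.0) == []

    def test_planted_consensus_found_at_its_position(self):
        # background of A's cannot reach the maximal score anywhere else
        seq = "A" * 37 + CONSENSUS + "A" * (200 - 37 - len(CONSENSUS))
        rec = SequenceRecord("planted", seq, 0)
        hits = scan_sequence(rec, ANCHOR_PWM, ANCHOR_PWM.max_score - 1e-9)
        assert [(h.start, h.strand) for h in hits] == [(37, "+")]
        assert hits[0].score == pytest.approx(ANCHOR_PWM.max_score)

    def test_planted_reverse_complement_reported_on_minus_strand(self):
        word = reverse_complement(CONSENSUS)
        seq = "A" * 37 + word + "A" * (200 - 37 - len(word))
        rec = SequenceRecord("planted_rc", seq, 0)
        hits = scan_sequence(rec, ANCHOR_PWM, ANCHOR_PWM.max_score - 1e-9)
        assert [(h.start, h.strand) for h in hits] == [(37, "-")]

    def test_matches_brute_force_on_both_strands(self):
        rng = np.random.default_rng(5)
        records = random_records(rng, 8, 300)
        for k in range(3):
            pwm = build_pwm(random_site_matrix(rng, f"M{k}"))
            threshold = 0.55 * pwm.max_score
            for rec in records:
                got = sorted((h.seq_id, h.start, h.strand, round(h.score, 9))
                             for h in scan_sequence(rec, pwm, threshold))
                assert got == brute_force_hits(rec, pwm, threshold)

    def test_windows_overlapping_n_are_discarded(self):
        seq = "A" * 30 + "N" + "A" * 30
        rec = SequenceRecord("withN", seq, 0)
        # permissive threshold: every N-free window is a hit
        hits = scan_sequence(rec, ANCHOR_PWM, ANCHOR_PWM.min_score - 1.0)
        m = ANCHOR_PWM.length
        starts = {h.start for h in hits}
        assert all(s + m <= 30 or s > 30 for s in starts)
        n_windows = len(seq) - m + 1
        assert len(starts) == n_windows - m  # m windows cover position 30

    def test_pwm_longer_than_sequence_gives_empty_list(self):
        rec = SequenceRecord("tiny", "ACGT", 0)
        assert scan_sequence(rec, ANCHOR_PWM, 0.0) == []

    def test_non_acgtn_character_is_an_error(self):
        rec = SequenceRecord("bad", "ACGTXACGTACGTACGT", 0)
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_sequence(rec, ANCHOR_PWM, 0.0)

    def test_hits_sorted_and_deterministic(self):
        rng = np.random.default_rng(6)
        rec = random_records(rng, 1, 400)[0]
        h1 = scan_sequence(rec, ANCHOR_PWM, 0.3 * ANCHOR_PWM.max_score)
        h2 = scan_sequence(rec, ANCHOR_PWM, 0.3 * ANCHOR_PWM.max_score)
        assert h1 == h2
        assert [h.start for h in h1] == sorted(h.start for h in h1)


class TestOccurrenceFrequency:
    def test_zero_numerator(self):
        assert compute_occurrence_frequency(0, 10, 100) == 0.0

    def test_direct_application(self):
        assert compute_occurrence_frequency(5, 10, 100) == pytest.approx(0.005)

    def test_target_gloss_one_hit_per_position_per_10000_sequences(self):
        assert compute_occurrence_frequency(1, 10000, 1) == pytest.approx(1e-4)

    def test_degenerate_l_rejected(self):
        with pytest.raises(ValueError, match="spans full sequence"):
            compute_occurrence_frequency(1, 10, 0)


class TestCalibration:
    def setup_method(self):
        self.rng = np.random.default_rng(7)

    def test_unreachable_start_returns_start_with_zero_ofr(self):
        # poly-A sequences never attain the maximal score of a sharp PWM
        records = [SequenceRecord(f"s{i}", "A" * 120, 0) for i in range(10)]
        res = calibrate_threshold(ANCHOR_PWM, records, target=0.01,
                                  floor=ANCHOR_PWM.max_score - 0.05)
        assert res.threshold == pytest.approx(ANCHOR_PWM.max_score)
        assert res.of_r == 0.0 and res.fP == 0

    def test_of_r_non_increasing_in_cutoff(self):
        records = random_records(self.rng, 30, 120)
        N, L = 30, 120 - ANCHOR_PWM.length
        cutoffs = np.linspace(0.0, ANCHOR_PWM.max_score, 12)
        ofs = [compute_occurrence_frequency(
            count_hits_in_set(records, ANCHOR_PWM, c), N, L) for c in cutoffs]
        assert all(a >= b for a, b in zip(ofs, ofs[1:]))

    def test_matches_exhaustive_grid_sweep(self):
        records = random_records(self.rng, 50, 120)
        pwm = build_pwm(random_site_matrix(self.rng, "M_CAL", length=8))
        target, step = 0.01, 0.1
        res = calibrate_threshold(pwm, records, target=target, step=step)
        N, L = 50, 120 - 8
        # oracle: evaluate OF_r at every grid point independently
        grid = []
        k = 0
        while pwm.max_score - k * step >= 0.0:
            c = pwm.max_score - k * step
            of = compute_occurrence_frequency(
                count_hits_in_set(records, pwm, c), N, L)
            grid.append((c, of))
            k += 1
        admissible = [c for c, of in grid if of <= target]
        assert res.threshold == pytest.approx(min(admissible))
        below = [of for c, of in grid if c < res.threshold - 1e-12]
        if below:  # minimality: the next lower grid point violates the target
            assert below[0] > target
        else:
            assert res.at_floor

    def test_threshold_self_consistency(self):
        records = random_records(self.rng, 40, 150)
        res = calibrate_threshold(ANCHOR_PWM, records, target=0.005)
        fP = count_hits_in_set(records, ANCHOR_PWM, res.threshold)
        assert fP == res.fP
        assert compute_occurrence_frequency(fP, res.N, res.L) == pytest.approx(res.of_r)

    def test_invalid_target_rejected(self):
        records = random_records(self.rng, 5, 60)
        with pytest.raises(ValueError, match="target"):
            calibrate_threshold(ANCHOR_PWM, records, target=0.0)

    def test_mixed_lengths_rejected(self):
        records = [SequenceRecord("a", "ACGT" * 30, 0),
                   SequenceRecord("b", "ACGT" * 40, 0)]
        with pytest.raises(ValueError, match="uniform length"):
            calibrate_threshold(ANCHOR_PWM, records)


def test_both_strand_scan_equals_forward_scan_of_both_orientations():
    rng = np.random.default_rng(8)
    rec = SequenceRecord("s", "".join(rng.choice(list("ACGT"), 250)), 0)
    threshold = 0.4 * ANCHOR_PWM.max_score
    both = {(h.start, h.strand, round(h.score, 9))
            for h in scan_sequence(rec, ANCHOR_PWM, threshold)}
    fwd = {(h.start, "+", round(h.score, 9))
           for h in scan_sequence(rec, ANCHOR_PWM, threshold, strands="forward")}
    rc_rec = SequenceRecord("s", reverse_complement(rec.sequence), 0)
    m, n = ANCHOR_PWM.length, len(rec.sequence)
    rev = {(n - h.start - m, "-", round(h.score, 9))
           for h in scan_sequence(rc_rec, ANCHOR_PWM, threshold, strands="forward")}
    assert both == fwd | rev
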