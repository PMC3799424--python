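"""Anchor-centered profiles, co-occurrence and positional-preference
statistics, window sweep, and CpG classification."""

import math

import numpy as np
import pytest
from scipy import stats

from crmscan.positional import (AnchorProfile, build_anchor_profile,
                                classify_cpg, cooccurrence_test,
                                exact_binomial_pvalue,
                                positional_preference_test, window_sweep)
from crmscan.scanner import Hit


def hit(seq_id, start, factor="F", strand="+"):
    return Hit(seq_id, start, strand, 1.0, factor)


def profile(counts_map, window, n_anchor, n_cooccur, anchor="A", partner="P"):
    counts = np.zeros(2 * window + 1)
    for d, c in counts_map.items():
        counts[d + window] = c
    return AnchorProfile(anchor, partner, window, counts, n_anchor, n_cooccur)


def random_hits(rng, n_seqs, factor, max_hits=3, length=500):
    hits = []
    for i in range(n_seqs):
        for _ in range(rng.integers(0, max_hits + 1)):
            hits.append(hit(f"s{i}", int(rng.integers(0, length)), factor))
    return hits


class TestAnchorProfile:
    def test_no_anchor_hits_gives_empty_profile(self):
        prof = build_anchor_profile([], [hit("s1", 10, "P")], window=100)
        assert prof.n_anchor_promoters == 0
        assert prof.n_cooccur == 0
        assert prof.counts.sum() == 0

    def test_hand_enumerated_two_promoters(self):
        anchors = [hit("s1", 50, "A"), hit("s2", 50, "A")]
        partners = [hit("s1", 60, "P"), hit("s2", 60, "P")]
        prof = build_anchor_profile(anchors, partners, window=100)
        assert prof.count_at(10) == 2
        assert prof.counts.sum() == 2
        assert prof.n_cooccur == 2
        assert prof.n_anchor_promoters == 2

    def test_domain_is_exactly_2w_plus_1_offsets(self):
        prof = build_anchor_profile([], [], window=100)
        assert prof.counts.shape == (201,)
        assert prof.offsets[0] == -100 and prof.offsets[-1] == 100

    def test_promoter_counted_once_per_offset(self):
        # two anchor/partner pairs in one promoter realizing the same offset
        anchors = [hit("s1", 50, "A"), hit("s1", 80, "A")]
        partners = [hit("s1", 60, "P"), hit("s1", 90, "P")]
        prof = build_anchor_profile(anchors, partners, window=100)
        assert prof.count_at(10) == 1
        assert prof.n_cooccur == 1

    def test_count_bounds_on_random_hit_sets(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            anchors = random_hits(rng, 30, "A")
            partners = random_hits(rng, 30, "P")
            prof = build_anchor_profile(anchors, partners, window=100)
            assert (prof.counts <= prof.n_cooccur).all()
            assert prof.counts.sum() >= prof.n_cooccur
            assert prof.n_cooccur <= prof.n_anchor_promoters

    def test_smoothed_copy_never_replaces_counts(self):
        anchors = [hit("s1", 50, "A")]
        partners = [hit("s1", 60, "P")]
        prof = build_anchor_profile(anchors, partners, window=20,
                                    smooth="running_mean_3")
        assert prof.count_at(10) == 1.0
        assert prof.smoothed is not None
        assert prof.smoothed[10 + 20] == pytest.approx(1 / 3)


class TestCooccurrence:
    def test_null_identity_gives_zero_z(self):
        obs = profile({0: 10}, 100, n_anchor=100, n_cooccur=10)
        ref = profile({0: 10}, 100, n_anchor=100, n_cooccur=10)
        res = cooccurrence_test(obs, ref)
        assert res.z == pytest.approx(0.0)
        assert not res.retained

    def test_hand_evaluated_z(self):
        # n=100, observed=50, background rate 0.1 -> z = 40 / 3
        obs = profile({0: 50}, 100, n_anchor=100, n_cooccur=50)
        ref = profile({0: 20}, 100, n_anchor=200, n_cooccur=20)
        res = cooccurrence_test(obs, ref)
        assert res.z == pytest.approx(40.0 / 3.0)
        assert res.retained

    def test_retained_strictly_above_three(self):
        # background rate 0.25 on n=300: tune observed around the z gate
        ref = profile({0: 50}, 100, n_anchor=200, n_cooccur=50)
        sd = math.sqrt(300 * 0.25 * 0.75)
        for obs_count, expected in [(int(75 + 2.99 * sd), False),
                                    (math.ceil(75 + 3.01 * sd), True)]:
            obs = profile({0: obs_count}, 100, 300, obs_count)
            assert cooccurrence_test(obs, ref).retained is expected

    def test_degenerate_background_requires_continuity_flag(self):
        obs = profile({0: 5}, 100, n_anchor=100, n_cooccur=5)
        ref = profile({}, 100, n_anchor=50, n_cooccur=0)
        with pytest.raises(ValueError, match="degenerate"):
            cooccurrence_test(obs, ref)
        res = cooccurrence_test(obs, ref, continuity=True)
        assert res.background_fraction == pytest.approx(0.5 / 50)
        assert res.z > 3

    def test_mismatched_windows_rejected(self):
        obs = profile({}, 100, 10, 0)
        ref = profile({}, 50, 10, 0)
        with pytest.raises(ValueError, match="window"):
            cooccurrence_test(obs, ref)


def oracle_tail_sum(k, n, p):
    """Exhaustive tail summation with exact integer binomial coefficients."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


class TestPositionalPreference:
    def test_null_identity_no_significant_positions(self):
        counts = {d: 5 for d in range(-100, 101)}
        obs = profile(counts, 100, n_anchor=100, n_cooccur=80)
        ref = profile(counts, 100, n_anchor=100, n_cooccur=80)
        calls = positional_preference_test(obs, ref)
        assert len(calls) == 201
        assert all(c.z == pytest.approx(0.0) for c in calls)
        assert not any(c.significant for c in calls)

    def test_exact_binomial_against_tail_sum_oracle(self):
        # spec example: n=100, k=10, p=0.01, plus a spread of other cases
        assert exact_binomial_pvalue(10, 100, 0.01) == pytest.approx(
            oracle_tail_sum(10, 100, 0.01), abs=1e-12)
        rng = np.random.default_rng(15)
        for _ in range(50):
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            p = float(rng.integers(1, 100)) / 100.0
            assert exact_binomial_pvalue(k, n, p) == pytest.approx(
                oracle_tail_sum(k, n, p), abs=1e-12)

    def test_z_gate_blocks_even_with_tiny_p(self):
        # large excess in absolute count but only ~6 sigma: p << 0.005, z < 10
        ref = profile({0: 300}, 100, n_anchor=1000, n_cooccur=300)
        n, p_hat = 1000, 0.3
        sd = math.sqrt(n * p_hat * (1 - p_hat))
        k = int(300 + 6 * sd)
        obs = profile({0: k}, 100, n_anchor=1000, n_cooccur=k)
        (call,) = [c for c in positional_preference_test(obs, ref) if c.offset == 0]
        assert call.p < 0.005 and call.z < 10
        assert not call.significant

    def test_joint_gate_passes_for_strong_preference(self):
        ref = profile({30: 1}, 100, n_anchor=500, n_cooccur=1)
        obs = profile({30: 60}, 100, n_anchor=500, n_cooccur=60)
        (call,) = [c for c in positional_preference_test(obs, ref)
                   if c.offset == 30]
        assert call.significant and call.z >= 10 and call.p < 0.005

    def test_background_zero_offsets_flagged_and_pseudocounted(self):
        obs = profile({5: 8}, 100, n_anchor=200, n_cooccur=8)
        ref = profile({}, 100, n_anchor=400, n_cooccur=0)
        calls = {c.offset: c for c in positional_preference_test(obs, ref)}
        assert calls[5].background_zero
        assert calls[5].expected == pytest.approx(200 * 0.5 / 400)
        assert calls[5].p == pytest.approx(
            oracle_tail_sum(8, 200, 0.5 / 400), abs=1e-12)
        assert not calls[6].background_zero and calls[6].p == 1.0

    def test_significance_definition_holds_on_random_profiles(self):
        rng = np.random.default_rng(16)
        ref_counts = {d: int(rng.integers(0, 20)) for d in range(-50, 51)}
        obs_counts = {d: int(rng.integers(0, 60)) for d in range(-50, 51)}
        obs = profile(obs_counts, 50, 200, 150)
        ref = profile(ref_counts, 50, 300, 200)
        for c in positional_preference_test(obs, ref):
            assert c.significant == (c.z >= 10 and c.p < 0.005)


class TestWindowSweep:
    def test_non_decreasing_in_window_size(self):
        rng = np.random.default_rng(17)
        anchors = random_hits(rng, 50, "A")
        partners = random_hits(rng, 50, "P")
        sweep = window_sweep(anchors, partners, windows=(100, 200, 500, 1000))
        values = [sweep[w] for w in (100, 200, 500, 1000)]
        assert values == sorted(values)

    def test_saturated_fixture_constant_across_windows(self):
        # every pair within +/-50: all four (total-width) windows identical
        anchors = [hit(f"s{i}", 500, "A") for i in range(20)]
        partners = [hit(f"s{i}", 500 + (i % 40) - 20, "P") for i in range(20)]
        sweep = window_sweep(anchors, partners, windows=(100, 200, 500, 1000))
        assert len(set(sweep.values())) == 1
        assert sweep[100] == 20

    def test_window_zero_counts_identical_starts_only(self):
        anchors = [hit("s1", 100, "A"), hit("s2", 100, "A")]
        partners = [hit("s1", 100, "P"), hit("s2", 101, "P")]
        sweep = window_sweep(anchors, partners, windows=(0, 10))
        assert sweep[0] == 1 and sweep[10] == 2

    def test_halfwidth_convention(self):
        anchors = [hit("s1", 100, "A")]
        partners = [hit("s1", 180, "P")]  # offset +80
        assert window_sweep(anchors, partners, windows=(100,))[100] == 0
        assert window_sweep(anchors, partners, windows=(100,),
                            halfwidth=True)[100] == 1

    def test_unsorted_windows_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            window_sweep([], [], windows=(500, 100))


class TestClassifyCpg:
    def test_poly_a_is_negative(self):
        assert classify_cpg("A" * 1000) == "CpG-"

    def test_cg_repeat_is_positive(self):
        # every 200-bp window: 100 C, 100 G, ~100 CG dinucleotides
        # obs/exp = (100 * 200) / (100 * 100) = 2 >= 0.6, GC fraction 1.0
        assert classify_cpg("CG" * 150) == "CpG+"

    def test_shorter_than_window_is_negative(self):
        assert classify_cpg("CG" * 99) == "CpG-"

    def test_gc_rich_without_cpg_dinucleotides_is_negative(self):
        # alternating C/A and G/T blocks: GC-rich but no CG dinucleotide
        seq = ("C" * 100 + "G" * 0 + "A" * 0 + "GC" * 0 + "T" * 0) * 1
        seq = ("CCAA" * 50 + "GGTT" * 50) * 2  # GC fraction 0.5, no CG dimers
        assert "CG" not in seq
        assert classify_cpg(seq) == "CpG-"

    def test_island_buried_in_at_background_is_found(self):
        seq = "AT" * 300 + "CG" * 120 + "TA" * 300
        assert classify_cpg(seq) == "CpG+"

    def test_windows_containing_n_are_skipped(self):
        # the only qualifying window would contain an N
        seq = "CG" * 100
        seq = seq[:100] + "N" + seq[101:]
        assert classify_cpg(seq) == "CpG-"
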