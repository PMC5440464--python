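"""PWM construction, log-odds scoring, exact score distribution and
information-content statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enharch import (
    BackgroundModel,
    Pwm,
    average_motif_hit_probability,
    build_pwm,
    information_content,
    log_odds_matrix,
    motif_hit_probability,
    score_distribution,
    score_sequence,
)
from enharch.motif import BASES, encode_sequence, reverse_complement
from enharch.synthetic import generate_pwm, sample_site


class TestBuildPwm:
    def test_pseudocount_formula_uniform_background(self, uniform_bg):
        pwm = build_pwm(np.array([[10.0, 0, 0, 0]]), uniform_bg)
        assert pwm.freqs[0, 0] == pytest.approx((10 + 0.0025) / 10.01)
        assert pwm.freqs[0, 1] == pytest.approx(0.0025 / 10.01)

    def test_pseudocount_formula_skewed_background(self, skewed_bg):
        # frequency-normalized column: mass 1 on A, q(A)=0.3
        pwm = build_pwm(np.array([[1.0, 0, 0, 0]]), skewed_bg)
        assert pwm.freqs[0, 0] == pytest.approx((1 + 0.003) / 1.01)
        assert pwm.freqs[0, 2] == pytest.approx(0.002 / 1.01)

    def test_rebuild_from_sampled_alignment(self, uniform_bg):
        # frequencies rebuilt from a 20-sequence sample stay within 3 sigma
        # of the generating PWM's (multinomial sampling error)
        truth = generate_pwm(8, 9.0, uniform_bg, seed=11, n_training=20)
        rebuilt = build_pwm(list(truth.training_alignment), uniform_bg)
        n = 20
        for i in range(truth.width):
            for b in range(4):
                p = truth.freqs[i, b]
                sigma = math.sqrt(p * (1 - p) / n)
                assert abs(rebuilt.freqs[i, b] - p) <= 3 * sigma + 0.01

    def test_accepts_4xL_layout(self, uniform_bg):
        counts = np.array([[5.0, 1], [1, 5], [1, 1], [1, 1]])  # 4 x 2
        pwm = build_pwm(counts, uniform_bg)
        assert pwm.width == 2
        assert pwm.freqs[0].argmax() == 0 and pwm.freqs[1].argmax() == 1

    @pytest.mark.parametrize(
        "bad",
        [
            [],  # empty alignment
            ["ACGN"],  # ambiguity code
            np.array([[-1.0, 2, 2, 2]]),  # negative counts
            np.array([[0.0, 0, 0, 0]]),  # zero column
        ],
    )
    def test_invalid_inputs_rejected(self, bad, uniform_bg):
        with pytest.raises(ValueError):
            build_pwm(bad, uniform_bg)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(6, 4)).astype(float) + rng.random((6, 4))
        counts[0] += 1  # guard against an all-zero column
        pwm = build_pwm(counts, BackgroundModel.uniform())
        np.testing.assert_allclose(pwm.freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pwm.freqs > 0)


class TestLogOdds:
    def test_background_identical_motif_scores_zero(self, uniform_bg):
        pwm = Pwm(name="flat", freqs=np.tile(uniform_bg.q, (5, 1)))
        assert np.allclose(log_odds_matrix(pwm, uniform_bg), 0.0)

    def test_single_cell_arithmetic(self, uniform_bg):
        freqs = np.array([[0.97, 0.01, 0.01, 0.01]])
        w = log_odds_matrix(Pwm(name="x", freqs=freqs), uniform_bg)
        assert w[0, 0] == pytest.approx(math.log2(0.97 / 0.25), abs=1e-12)

    def test_argmax_string_is_max_scoring_by_enumeration(self, skewed_bg):
        pwm = generate_pwm(4, 5.0, skewed_bg, seed=3)
        w = log_odds_matrix(pwm, skewed_bg)
        best = max(
            ("".join(s) for s in itertools.product(BASES, repeat=4)),
            key=lambda s: sum(w[i, BASES.index(c)] for i, c in enumerate(s)),
        )
        assert best == pwm.consensus()


class TestScoreSequence:
    def test_consensus_hits_maximum_at_offset_zero(self, uniform_bg):
        pwm = generate_pwm(6, 10.0, uniform_bg, seed=5)
        w = log_odds_matrix(pwm, uniform_bg)
        hits = score_sequence(w, pwm.consensus(), strands="forward")
        assert len(hits) == 1
        off, strand, score = hits[0]
        assert (off, strand) == (0, "+")
        assert score == pytest.approx(w.max(axis=1).sum())

    def test_palindromic_matrix_scores_both_strands_equally(self, uniform_bg):
        col = np.array([0.7, 0.1, 0.1, 0.1])
        rc_col = col[::-1]  # complement order T,G,C,A
        freqs = np.vstack([col, rc_col])
        w = log_odds_matrix(Pwm(name="pal", freqs=freqs), uniform_bg)
        hits = score_sequence(w, "ATGCATGCAT", strands="both")
        by_offset = {}
        for off, strand, score in hits:
            by_offset.setdefault(off, {})[strand] = score
        for scores in by_offset.values():
            assert scores["+"] == pytest.approx(scores["-"], abs=1e-12)

    def test_random_sequence_matches_naive_window_sums(self, uniform_bg):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list(BASES), 50))
        pwm = generate_pwm(5, 7.0, uniform_bg, seed=8)
        w = log_odds_matrix(pwm, uniform_bg)
        hits = score_sequence(w, seq, strands="both")
        assert len(hits) == 46 * 2
        for off, strand, score in hits:
            window = seq[off : off + 5]
            if strand == "-":
                window = reverse_complement(window)
            naive = sum(w[i, BASES.index(c)] for i, c in enumerate(window))
            assert score == pytest.approx(naive, abs=1e-9)

    def test_ambiguous_windows_are_skipped(self, uniform_bg):
        pwm = generate_pwm(4, 6.0, uniform_bg, seed=9)
        w = log_odds_matrix(pwm, uniform_bg)
        hits = score_sequence(w, "ACGTNACGT", strands="forward")
        offsets = {off for off, _, _ in hits}
        assert offsets == {0, 5}  # windows touching the N are unscored

    def test_too_short_sequence_raises(self, uniform_bg):
        pwm = generate_pwm(6, 6.0, uniform_bg, seed=1)
        with pytest.raises(ValueError, match="shorter"):
            score_sequence(log_odds_matrix(pwm, uniform_bg), "ACG")


class TestScoreDistribution:
    def test_single_position_enumeration(self, uniform_bg):
        # near-deterministic single column: top score occurs for one base
        freqs = np.array([[0.97, 0.01, 0.01, 0.01]])
        w = log_odds_matrix(Pwm(name="x", freqs=freqs), uniform_bg)
        dist = score_distribution(w, uniform_bg)
        assert dist.ln_pvalue(w.max()) == pytest.approx(math.log(0.25), abs=1e-9)
        assert dist.ln_pvalue(w.min()) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("L", [2, 3, 4, 5, 6])
    def test_matches_full_enumeration(self, L, skewed_bg):
        pwm = generate_pwm(L, 1.3 * L, skewed_bg, seed=L)
        w = log_odds_matrix(pwm, skewed_bg)
        bin_width = 0.01
        dist = score_distribution(w, skewed_bg, bin_width)
        # oracle: enumerate all 4**L strings on the same integer grid
        iw = np.rint(w / bin_width).astype(int)
        exact = {}
        for codes in itertools.product(range(4), repeat=L):
            s = sum(iw[i, c] for i, c in enumerate(codes))
            pr = math.prod(skewed_bg.q[c] for c in codes)
            exact[s] = exact.get(s, 0.0) + pr
        scores = sorted(exact)
        for threshold in scores:
            tail = sum(pr for s, pr in exact.items() if s >= threshold)
            got = dist.ln_pvalue(threshold * bin_width)
            assert got == pytest.approx(math.log(tail), abs=1e-9)

    def test_tail_at_maximum_equals_consensus_probability(self, skewed_bg):
        pwm = generate_pwm(5, 8.0, skewed_bg, seed=4)
        w = log_odds_matrix(pwm, skewed_bg)
        dist = score_distribution(w, skewed_bg)
        consensus_prob = math.prod(skewed_bg.q[b] for b in pwm.freqs.argmax(axis=1))
        assert dist.ln_pvalue(w.max(axis=1).sum()) == pytest.approx(
            math.log(consensus_prob), abs=0.05
        )

    def test_ln_pvalue_is_non_increasing(self, uniform_bg):
        pwm = generate_pwm(7, 9.0, uniform_bg, seed=12)
        dist = score_distribution(log_odds_matrix(pwm, uniform_bg), uniform_bg)
        finite = dist.ln_tail[np.isfinite(dist.ln_tail)]
        assert np.all(np.diff(finite) <= 1e-12)

    def test_rejects_bad_bin_width(self, uniform_bg):
        pwm = generate_pwm(4, 5.0, uniform_bg, seed=2)
        with pytest.raises(ValueError):
            score_distribution(log_odds_matrix(pwm, uniform_bg), uniform_bg, bin_width=0)


class TestInformationContent:
    def test_zero_for_background_identical_motif(self, skewed_bg):
        pwm = Pwm(name="flat", freqs=np.tile(skewed_bg.q, (6, 1)))
        assert information_content(pwm, skewed_bg) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_motif_with_pseudocount(self, uniform_bg):
        # 5 columns of count 1 on a single base, pseudocount total 0.01:
        # oracle = direct formula at the pseudocounted frequencies
        counts = np.zeros((5, 4))
        counts[:, 0] = 1.0
        pwm = build_pwm(counts, uniform_bg)
        pa = (1 + 0.0025) / 1.01
        po = 0.0025 / 1.01
        per_col = pa * math.log2(pa / 0.25) + 3 * po * math.log2(po / 0.25)
        expected = 5 * per_col
        assert information_content(pwm, uniform_bg) == pytest.approx(expected, abs=1e-12)
        # with single-observation columns the pseudocount correction is ~0.37 bits
        assert expected == pytest.approx(10.0, abs=0.5)

    def test_content_to_hit_probability_anchors(self):
        assert motif_hit_probability(-math.log2(2e-3)) == pytest.approx(2e-3, rel=1e-12)
        assert motif_hit_probability(14.02) == pytest.approx(6e-5, rel=0.01)
        assert motif_hit_probability(0.0) == 1.0
        assert motif_hit_probability(10.0) == pytest.approx(9.77e-4, rel=1e-3)

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError):
            motif_hit_probability(-0.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_information_content_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=(5, 4)).astype(float)
        bg = BackgroundModel.uniform()
        assert information_content(build_pwm(counts, bg), bg) >= -1e-12


class TestAverageHitProbability:
    def test_single_tf_degenerate_average(self):
        assert average_motif_hit_probability([7], [10.0]) == pytest.approx(2**-10.0)

    def test_equal_counts_arithmetic_mean(self):
        got = average_motif_hit_probability([4, 4], [8.0, 10.0])
        assert got == pytest.approx((2**-8 + 2**-10) / 2)

    def test_weighted_mean_hand_summation(self):
        n, I = [3, 1], [8.97, 14.02]
        expected = (3 * 2**-8.97 + 1 * 2**-14.02) / 4
        assert average_motif_hit_probability(n, I) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_uniform_count_scaling(self):
        a = average_motif_hit_probability([3, 1, 2], [8.0, 9.0, 12.0])
        b = average_motif_hit_probability([30, 10, 20], [8.0, 9.0, 12.0])
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounded_by_extreme_hit_probabilities(self):
        got = average_motif_hit_probability([5, 2, 9], [7.0, 11.0, 9.0])
        assert 2**-11.0 <= got <= 2**-7.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            average_motif_hit_probability([0, 0], [8.0, 9.0])


def test_encode_and_reverse_complement_roundtrip():
    seq = "ACGTACGT"
    assert reverse_complement(reverse_complement(seq)) == seq
    assert list(encode_sequence("ACGTn")) == [0, 1, 2, 3, -1]
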