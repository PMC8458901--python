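"""PWM parsing, scoring, scanning and top-word enumeration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifimpact.alphabet import revcomp
from motifimpact.pwm import (
    PWM,
    max_window_probability,
    parse_pwm,
    pwm_probability,
    pwm_score,
    relative_entropy,
    scan_sequence,
    top_scoring_kmers,
)

from .conftest import random_pwm, random_sequence

UNIFORM3 = PWM(np.full((3, 4), 0.25))
ACGT_DET = PWM(np.eye(4)[[0, 1, 2, 3]], motif_id="acgt")  # deterministic ACGT


def brute_force_probability(pwm: PWM, seq: str) -> float:
    """Independent per-position product, pure Python."""
    lookup = {b: j for j, b in enumerate("ACGT")}
    return math.prod(pwm.probs[i][lookup[c]] for i, c in enumerate(seq))


class TestParse:
    def test_uniform_counts_normalize_to_quarter(self):
        text = "10 10\n10 10\n10 10\n10 10\n"
        pwm = parse_pwm(text)
        assert pwm.length == 2
        np.testing.assert_allclose(pwm.probs, 0.25)

    def test_probability_matrix_unchanged(self, rng):
        mat = rng.dirichlet(np.ones(4), size=5)
        text = "\n".join(" ".join(f"{v:.12f}" for v in row) for row in mat.T)
        pwm = parse_pwm(text)
        np.testing.assert_allclose(pwm.probs, mat / mat.sum(axis=1, keepdims=True), atol=1e-9)

    def test_counts_with_zero_pseudocount(self):
        text = "97\n1\n1\n1\n"
        pwm = parse_pwm(text, pseudocount=0.0)
        assert pwm.probs[0, 0] == pytest.approx(0.97)

    def test_jaspar_labelled_rows_with_brackets(self):
        text = ">MA0000.1 TEST\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        pwm = parse_pwm(text, pseudocount=0.0)
        assert pwm.motif_id == "MA0000.1"
        np.testing.assert_allclose(pwm.probs[0], [1, 0, 0, 0])
        np.testing.assert_allclose(pwm.probs[1], [0, 1, 0, 0])

    def test_labelled_rows_out_of_order_are_reordered(self):
        text = "T 0 0\nG 0 0\nC 0 10\nA 10 0\n"
        pwm = parse_pwm(text, pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs[0], [1, 0, 0, 0])

    def test_orientation_autodetect_l_by_4(self, rng):
        mat = rng.dirichlet(np.ones(4), size=6)
        text = "\n".join(" ".join(map(str, row)) for row in mat)
        assert parse_pwm(text).length == 6

    @pytest.mark.parametrize(
        "text, match",
        [
            ("1 2 3\n1 2\n1 2 3\n1 2 3", "inconsistent"),
            ("1 2\n-1 2\n1 2\n1 2", "negative"),
            ("1 x\n1 2\n1 2\n1 2", "malformed"),
        ],
    )
    def test_malformed_matrices_name_offending_row(self, text, match):
        with pytest.raises(ValueError, match=match):
            parse_pwm(text)

    def test_parse_is_idempotent_on_normalized_output(self, rng):
        pwm = random_pwm(rng, 7)
        text = "\n".join(" ".join(f"{v:.15g}" for v in row) for row in pwm.probs)
        again = parse_pwm(text)
        np.testing.assert_allclose(again.probs, pwm.probs, atol=1e-9)


class TestProbabilityAndScore:
    def test_uniform_trimer(self):
        assert pwm_probability(UNIFORM3, "GTA") == pytest.approx(0.25**3)

    def test_deterministic_consensus(self):
        assert pwm_probability(ACGT_DET, "ACGT") == 1.0
        assert pwm_score(ACGT_DET, "ACGT") == 0.0

    def test_zero_probability_base_annihilates(self):
        assert pwm_probability(ACGT_DET, "TCGT") == 0.0
        assert pwm_score(ACGT_DET, "TCGT") == math.inf

    def test_uniform_ten_score_closed_form(self):
        pwm = PWM(np.full((10, 4), 0.25))
        assert pwm_score(pwm, "ACGTACGTAC") == pytest.approx(10 * math.log(4))

    def test_score_of_probability_tenth(self):
        pwm = PWM(np.array([[0.1, 0.3, 0.3, 0.3]]))
        assert pwm_score(pwm, "A") == pytest.approx(2.302585, abs=1e-6)

    @pytest.mark.parametrize("seq", ["AC", "ACGTA", "ACN"])
    def test_length_mismatch_or_ambiguous_raise(self, seq):
        with pytest.raises(ValueError):
            pwm_probability(UNIFORM3, seq)

    def test_strand_convention_invariance(self, rng):
        pwm = random_pwm(rng, 9)
        for _ in range(20):
            seq = random_sequence(rng, 9)
            assert pwm_probability(pwm, seq) == pytest.approx(
                pwm_probability(pwm.reverse_complement(), revcomp(seq))
            )


class TestWindowedScoring:
    def test_uniform_long_motif_all_alignments_equal(self):
        pwm = PWM(np.full((15, 4), 0.25))
        assert max_window_probability(pwm, "ACGTACGTAC") == pytest.approx(0.25**10)

    def test_equal_length_reduces_to_full_probability(self, rng):
        pwm = random_pwm(rng, 10)
        seq = random_sequence(rng, 10)
        assert max_window_probability(pwm, seq) == pytest.approx(pwm_probability(pwm, seq))

    def test_matches_exhaustive_window_enumeration(self, rng):
        pwm = random_pwm(rng, 15)
        for _ in range(20):
            seq = random_sequence(rng, 10)
            oracle = max(
                brute_force_probability(PWM(pwm.probs[o : o + 10]), seq)
                for o in range(6)
            )
            assert max_window_probability(pwm, seq) == pytest.approx(oracle)

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            max_window_probability(UNIFORM3, "ACGTACGTAC")


class TestRelativeEntropy:
    def test_uniform_pwm_gives_zero(self, rng):
        pwm = PWM(np.full((6, 4), 0.25))
        assert relative_entropy(pwm, random_sequence(rng, 6)) == pytest.approx(0.0)

    def test_deterministic_consensus_ten_ln_four(self):
        probs = np.tile(np.eye(4)[0], (10, 1))
        pwm = PWM(probs)
        assert relative_entropy(pwm, "A" * 10) == pytest.approx(10 * math.log(4))

    def test_zero_probability_position_contributes_zero(self):
        probs = np.vstack([[0.0, 1 / 3, 1 / 3, 1 / 3], np.full((4, 4), 0.25)])
        pwm = PWM(probs)
        assert relative_entropy(pwm, "AAAAA") == pytest.approx(0.0)

    def test_negate_flag_flips_sign(self, rng):
        pwm = random_pwm(rng, 5)
        seq = random_sequence(rng, 5)
        assert relative_entropy(pwm, seq, negate=True) == pytest.approx(
            -relative_entropy(pwm, seq)
        )

    def test_log_base_rescales(self, rng):
        pwm = random_pwm(rng, 5)
        seq = random_sequence(rng, 5)
        assert relative_entropy(pwm, seq, base=2) == pytest.approx(
            relative_entropy(pwm, seq) / math.log(2)
        )


class TestScan:
    def test_embedded_consensus_found(self):
        sites = scan_sequence(ACGT_DET, "TTACGTTT", 0.5, strands="+")
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.strand, s.probability) == (2, 6, "+", 1.0)

    def test_uniform_pwm_threshold_one_empty(self):
        pwm = PWM(np.full((4, 4), 0.25))
        assert scan_sequence(pwm, "ACGTACGTACGT", 1.0) == []

    def test_windows_with_ambiguous_bases_skipped(self):
        sites = scan_sequence(ACGT_DET, "ACNTACGT", 0.01, strands="+")
        assert [s.start for s in sites] == [4]

    def test_short_sequence_yields_empty(self):
        assert scan_sequence(ACGT_DET, "ACG", 0.5) == []

    def test_matches_brute_force_both_strands(self, rng):
        pwm = random_pwm(rng, 8)
        seq = random_sequence(rng, 2000)
        threshold = float(np.quantile(
            [brute_force_probability(pwm, seq[i : i + 8]) for i in range(200)], 0.9
        ))
        sites = scan_sequence(pwm, seq, threshold)
        expected = set()
        for start in range(len(seq) - 7):
            window = seq[start : start + 8]
            if brute_force_probability(pwm, window) >= threshold:
                expected.add((start, "+"))
            if brute_force_probability(pwm, revcomp(window)) >= threshold:
                expected.add((start, "-"))
        assert {(s.start, s.strand) for s in sites} == expected


class TestTopKmers:
    def test_deterministic_pwm_consensus_first(self):
        probs = np.tile(np.eye(4)[[0, 1, 2, 3]], (3, 1))[:10]
        pwm = PWM(probs)
        (kmer, prob), = top_scoring_kmers(pwm, 10, 1)
        assert kmer == pwm.consensus and prob == pytest.approx(1.0)

    def test_uniform_ties_break_lexicographically(self):
        pwm = PWM(np.full((10, 4), 0.25))
        top = top_scoring_kmers(pwm, 10, 3)
        assert [k for k, _ in top] == ["AAAAAAAAAA", "AAAAAAAAAC", "AAAAAAAAAG"]
        assert all(p == pytest.approx(0.25**10) for _, p in top)

    def test_matches_brute_force_enumeration(self, rng):
        pwm = random_pwm(rng, 8)
        word = 6
        scored = sorted(
            (
                (-max(
                    brute_force_probability(PWM(pwm.probs[o : o + word]), kmer)
                    for o in range(pwm.length - word + 1)
                ), kmer)
                for kmer in map(
                    lambda c: "".join("ACGT"[(c // 4**j) % 4] for j in reversed(range(word))),
                    range(4**word),
                )
            ),
        )
        expected = [(k, -p) for p, k in scored[:50]]
        got = top_scoring_kmers(pwm, word, 50)
        assert [k for k, _ in got] == [k for k, _ in expected]
        np.testing.assert_allclose([p for _, p in got], [p for _, p in expected])


@given(st.text(alphabet="ACGT", min_size=6, max_size=6))
def test_probability_times_score_consistency(seq):
    """pwm_score is exactly the negative log of pwm_probability."""
    pwm = PWM(np.full((6, 4), 0.25))
    assert pwm_score(pwm, seq) == pytest.approx(-math.log(pwm_probability(pwm, seq)))
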