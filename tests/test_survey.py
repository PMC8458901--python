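"""Survey-level analyses: SNV selection, LD expansion, overlap,
discordance accounting, correlation and ROC/PRC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from motifimpact.calibration import ThresholdPair
from motifimpact.delta import DeltaResult
from motifimpact.gkm import KmerWeightTable
from motifimpact.io import SnvRecord
from motifimpact.pwm import PWM, MotifSite
from motifimpact.survey import (
    AssociationRecord,
    correlation_pwm_vs_svm,
    discordance_matrix,
    discordance_table,
    expand_ld_window,
    overlap_with_motif_sites,
    rank_auc_roc,
    roc_prc_comparison,
    select_index_snvs,
)

from .conftest import random_sequence


def assoc(snv_id, pos, p, trait="t", chrom="chr1"):
    return AssociationRecord(snv_id, chrom, pos, p, trait)


def snv(pos, snv_id=None, chrom="chr1"):
    return SnvRecord(chrom, pos, "A", "C", id=snv_id or f"rs{pos}")


class TestSelectIndex:
    def test_inclusive_boundary(self):
        records = [assoc("a", 1, 1e-5), assoc("b", 2, 1e-6), assoc("c", 3, 1e-7)]
        kept = select_index_snvs(records)
        assert [r.snv_id for r in kept] == ["b", "c"]

    def test_empty_and_dedup(self):
        assert select_index_snvs([]) == []
        dup = [assoc("a", 1, 1e-8), assoc("a", 1, 1e-9)]
        assert len(select_index_snvs(dup)) == 1

    def test_same_snv_two_traits_kept_twice(self):
        recs = [assoc("a", 1, 1e-8, "t1"), assoc("a", 1, 1e-8, "t2")]
        assert len(select_index_snvs(recs)) == 2

    def test_accepts_dataframe(self):
        df = pd.DataFrame(
            {"snv_id": ["a"], "chrom": ["chr1"], "pos": [5], "p_value": [1e-9], "trait": ["t"]}
        )
        assert select_index_snvs(df)[0].snv_id == "a"


class TestExpandLd:
    def test_inclusive_window_bounds(self):
        index = [assoc("i", 10_000, 1e-8)]
        snvs = [snv(5000), snv(15_000), snv(15_001), snv(4999)]
        got = expand_ld_window(index, snvs, window=5000)
        assert [s.pos for s in got] == [5000, 15_000]

    def test_zero_window_keeps_colocated_only(self):
        index = [assoc("i", 100, 1e-8)]
        snvs = [snv(100), snv(101)]
        assert [s.pos for s in expand_ld_window(index, snvs, 0)] == [100]

    def test_chromosome_must_match(self):
        index = [assoc("i", 100, 1e-8, chrom="chr2")]
        assert expand_ld_window(index, [snv(100)], 5000) == []

    def test_matches_quadratic_oracle_and_monotonicity(self, rng):
        index = [assoc(f"i{k}", int(p), 1e-8) for k, p in enumerate(rng.integers(0, 50_000, 8))]
        snvs = [snv(int(p), f"s{j}") for j, p in enumerate(rng.integers(0, 50_000, 200))]
        small = expand_ld_window(index, snvs, 1000)
        large = expand_ld_window(index, snvs, 4000)
        oracle = sorted(
            {s.pos for s in snvs if any(abs(s.pos - i.pos) <= 4000 for i in index)}
        )
        assert sorted(s.pos for s in large) == oracle
        assert set(s.pos for s in small) <= set(s.pos for s in large)


class TestOverlap:
    def test_half_open_membership(self):
        site = MotifSite("chr1", 10, 15, "+", 0.5)
        annotated = overlap_with_motif_sites([snv(10), snv(14), snv(15)], [site])
        hits = [len(sites) for _, sites in annotated]
        assert hits == [1, 1, 0]

    def test_empty_sites(self):
        assert overlap_with_motif_sites([snv(5)], [])[0][1] == []

    def test_matches_brute_force(self, rng):
        sites = [
            MotifSite("chr1", int(s), int(s) + 12, "+", 0.5)
            for s in rng.integers(0, 10_000, 100)
        ]
        snvs = [snv(int(p), f"s{j}") for j, p in enumerate(rng.integers(0, 10_000, 1000))]
        annotated = overlap_with_motif_sites(snvs, sites)
        for s, hits in annotated:
            brute = [t for t in sites if t.start <= s.pos < t.end]
            assert sorted(hits, key=lambda x: (x.start, x.strand)) == sorted(
                brute, key=lambda x: (x.start, x.strand)
            )


def make_delta(pos, dsvm, in_site=True, snv_id=None):
    s = snv(pos, snv_id)
    site = MotifSite("chr1", pos - 2, pos + 3, "+", 0.9) if in_site else None
    return DeltaResult(snv=s, delta_svm=dsvm, delta_pwm=0.1 if in_site else None, motif_site=site)


class TestDiscordance:
    thr = ThresholdPair(lower=-1.0, upper=1.0)

    def test_eighty_percent_discordant(self):
        deltas = [make_delta(100 + i, 2.0 if i < 2 else 0.0, snv_id=f"r{i}") for i in range(10)]
        traits = {f"r{i}": {"asthma"} for i in range(10)}
        df = discordance_table(deltas, self.thr, traits, tf="TF1")
        row = df.iloc[0]
        assert row["n_overlapping"] == 10 and row["n_discordant"] == 8
        assert row["percent_discordant"] == pytest.approx(80.0)

    def test_all_significant_gives_zero(self):
        deltas = [make_delta(100 + i, 5.0, snv_id=f"r{i}") for i in range(4)]
        traits = {f"r{i}": {"t"} for i in range(4)}
        df = discordance_table(deltas, self.thr, traits, tf="TF")
        assert df.iloc[0]["percent_discordant"] == 0.0

    def test_zero_overlap_percentage_absent(self):
        deltas = [make_delta(100, 0.0, in_site=False, snv_id="r0")]
        traits = {"r0": {"t"}}
        df = discordance_table(deltas, self.thr, traits, tf="TF")
        assert df.iloc[0]["n_overlapping"] == 0
        assert np.isnan(df.iloc[0]["percent_discordant"])

    def test_concordance_complement(self):
        deltas = [make_delta(100 + i, 2.0 if i % 3 == 0 else 0.0, snv_id=f"r{i}") for i in range(9)]
        traits = {f"r{i}": {"t"} for i in range(9)}
        df = discordance_table(deltas, self.thr, traits, tf="TF")
        pct = df.iloc[0]["percent_discordant"]
        concordant = 100.0 * (df.iloc[0]["n_overlapping"] - df.iloc[0]["n_discordant"]) / df.iloc[0]["n_overlapping"]
        assert pct + concordant == pytest.approx(100.0)

    def test_wide_matrix_layout(self):
        deltas = [make_delta(100, 0.0, snv_id="r0")]
        df = discordance_table(deltas, self.thr, {"r0": {"t1", "t2"}}, tf="TF")
        wide = discordance_matrix(df)
        assert wide.shape == (1, 2)


class TestCorrelation:
    def test_affine_weights_give_unit_correlation(self, rng):
        pwm = PWM(rng.dirichlet(np.ones(4), size=6))
        from motifimpact.pwm import top_scoring_kmers
        from motifimpact.alphabet import kmer_to_code

        weights = np.zeros(4**6)
        for kmer, p in top_scoring_kmers(pwm, 6, 4**6):
            weights[kmer_to_code(kmer)] = 3.0 * p + 1.0
        table = KmerWeightTable(6, weights)
        assert correlation_pwm_vs_svm(pwm, table, top_n=500) == pytest.approx(1.0)

    def test_constant_weights_undefined(self, rng):
        pwm = PWM(rng.dirichlet(np.ones(4), size=6))
        table = KmerWeightTable(6, np.ones(4**6))
        assert np.isnan(correlation_pwm_vs_svm(pwm, table, top_n=100))

    def test_matches_textbook_pearson(self, rng):
        from motifimpact.pwm import top_scoring_kmers

        pwm = PWM(rng.dirichlet(np.ones(4), size=6))
        table = KmerWeightTable(6, rng.normal(size=4**6))
        n = 200
        got = correlation_pwm_vs_svm(pwm, table, top_n=n)
        top = top_scoring_kmers(pwm, 6, n)
        x = np.array([p for _, p in top])
        y = np.array([table.weight(k) for k, _ in top])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_spearman_option(self, rng):
        pwm = PWM(rng.dirichlet(np.ones(4), size=6))
        table = KmerWeightTable(6, rng.normal(size=4**6))
        r = correlation_pwm_vs_svm(pwm, table, top_n=100, method="spearman")
        assert -1.0 <= r <= 1.0


def pair_count_auc(pos, neg):
    """Exhaustive concordant-pair oracle with half-credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocPrc:
    def test_worked_five_sequence_example(self):
        assert rank_auc_roc([0.9, 0.8, 0.3], [0.7, 0.2]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert rank_auc_roc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_all_tied_scores(self):
        assert rank_auc_roc([1, 1, 1], [1, 1]) == 0.5

    def test_matches_pair_counting_on_random_sets(self, rng):
        for _ in range(20):
            n_pos = int(rng.integers(2, 26))
            n_neg = int(rng.integers(2, 26))
            pos = rng.integers(0, 10, size=n_pos).astype(float)  # ties likely
            neg = rng.integers(0, 10, size=n_neg).astype(float)
            assert rank_auc_roc(pos, neg) == pytest.approx(pair_count_auc(pos, neg))

    def test_sequence_scoring_comparison(self, rng):
        pwm = PWM(np.tile(np.eye(4)[[0, 1, 2, 3]], (2, 1)))  # strict ACGTACGT
        consensus = "ACGTACGT"
        pos = []
        for _ in range(15):
            s = random_sequence(rng, 60)
            at = int(rng.integers(0, 52))
            pos.append(s[:at] + consensus + s[at + 8 :])
        neg = [random_sequence(rng, 60).replace(consensus, "ACGTACGA") for _ in range(15)]
        weights = np.zeros(4**6)
        from motifimpact.alphabet import kmer_to_code

        weights[kmer_to_code("ACGTAC")] = 5.0
        weights[kmer_to_code("CGTACG")] = 5.0
        table = KmerWeightTable(6, weights)
        out = roc_prc_comparison(pos, neg, pwm, table, summarize="maximum")
        assert out["pwm"]["auc_roc"] == 1.0
        assert out["svm"]["auc_roc"] == 1.0
        assert out["pwm"]["auc_prc"] == 1.0

    def test_short_sequences_excluded(self, rng):
        pwm = PWM(np.full((8, 4), 0.25))
        table = KmerWeightTable(6, np.zeros(4**6))
        pos = [random_sequence(rng, 30), "ACGT"]
        neg = [random_sequence(rng, 30)]
        out = roc_prc_comparison(pos, neg, pwm, table)
        assert out["n_excluded"] == 1
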