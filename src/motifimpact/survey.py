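"""Results-level analyses: disease-locus SNV selection, motif overlap,
discordant-SNV accounting, PWM-vs-SVM correlation, and ROC/PRC comparison.

The central quantity is the *discordant SNV*: a variant that lies inside a
PWM-called putative binding site yet whose deltaSVM score does not exceed the
empirical significance thresholds — i.e. a variant the classical PWM
annotation would flag as consequential but the in-vivo-trained SVM does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .calibration import ThresholdPair, is_significant
from .delta import DeltaResult
from .gkm import KmerWeightTable, sequence_svm_score
from .io import SnvRecord
from .pwm import PWM, MotifSite, top_scoring_kmers, window_probabilities

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "DiscordanceCell",
    "select_index_snvs",
    "expand_ld_window",
    "assign_traits",
    "overlap_with_motif_sites",
    "discordance_table",
    "discordance_matrix",
    "correlation_pwm_vs_svm",
    "rank_auc_roc",
    "roc_prc_comparison",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-trait association (a GWAS catalogue row)."""

    snv_id: str
    chrom: str
    pos: int
    p_value: float
    trait: str

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class DiscordanceCell:
    """Discordant-SNV accounting for one (TF, trait) pair."""

    tf: str
    trait: str
    n_overlapping: int
    n_discordant: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_discordant <= self.n_overlapping):
            raise ValueError("require 0 <= n_discordant <= n_overlapping")

    @property
    def percent_discordant(self) -> float | None:
        if self.n_overlapping == 0:
            return None
        return 100.0 * self.n_discordant / self.n_overlapping


def _as_records(assocs) -> list[AssociationRecord]:
    if isinstance(assocs, pd.DataFrame):
        return [
            AssociationRecord(
                str(r.snv_id), str(r.chrom), int(r.pos), float(r.p_value), str(r.trait)
            )
            for r in assocs.itertuples()
        ]
    return list(assocs)


def select_index_snvs(assocs, p_threshold: float = 1e-6) -> list[AssociationRecord]:
    """Keep associations with p <= threshold (inclusive boundary),
    deduplicated by (snv_id, trait), in input order."""
    seen = set()
    out = []
    for rec in _as_records(assocs):
        if rec.p_value <= p_threshold and (rec.snv_id, rec.trait) not in seen:
            seen.add((rec.snv_id, rec.trait))
            out.append(rec)
    return out


def expand_ld_window(
    index_snvs: list[AssociationRecord],
    all_snvs: list[SnvRecord],
    window: int = 5000,
) -> list[SnvRecord]:
    """Every SNV within +/- ``window`` bp (inclusive) of any index SNV on the
    same chromosome — the positional LD proxy — deduplicated and sorted by
    (chrom, pos)."""
    by_chrom: dict[str, list[int]] = {}
    for idx in index_snvs:
        by_chrom.setdefault(idx.chrom, []).append(idx.pos)
    out = {}
    for snv in all_snvs:
        positions = by_chrom.get(snv.chrom)
        if positions and any(abs(snv.pos - p) <= window for p in positions):
            out[(snv.chrom, snv.pos, snv.ref, snv.alt)] = snv
    return sorted(out.values(), key=lambda s: (s.chrom, s.pos))


def assign_traits(
    index_snvs: list[AssociationRecord],
    snvs: list[SnvRecord],
    window: int = 5000,
) -> dict[str, set[str]]:
    """Map each SNV id to the traits whose index-SNV windows contain it
    (a SNV near two index SNVs of the same trait counts once per trait)."""
    traits: dict[str, set[str]] = {}
    for snv in snvs:
        for idx in index_snvs:
            if idx.chrom == snv.chrom and abs(idx.pos - snv.pos) <= window:
                traits.setdefault(snv.id, set()).add(idx.trait)
    return traits


def overlap_with_motif_sites(
    snvs: list[SnvRecord], sites: list[MotifSite]
) -> list[tuple[SnvRecord, list[MotifSite]]]:
    """Annotate each SNV with the putative sites containing it (half-open
    membership: start <= pos < end), via an interval tree."""
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s)
    annotated = []
    for snv in snvs:
        tree = trees.get(snv.chrom)
        hits = (
            sorted((iv.data for iv in tree[snv.pos]), key=lambda s: (s.start, s.strand))
            if tree is not None
            else []
        )
        annotated.append((snv, hits))
    return annotated


def discordance_table(
    deltas: list[DeltaResult],
    thr: ThresholdPair,
    traits: dict[str, set[str]],
    tf: str,
) -> pd.DataFrame:
    """Per-trait discordant-SNV counts for one TF.

    For each trait: ``n_overlapping`` counts SNVs attached to a motif site,
    ``n_discordant`` those whose deltaSVM is *not* significant against the
    empirical thresholds. ``percent_discordant`` is NaN (absent) for traits
    with zero overlapping SNVs. Also fills each result's ``significant``
    flag in place.
    """
    all_traits = sorted({t for ts in traits.values() for t in ts})
    cells = {t: [0, 0] for t in all_traits}  # trait -> [n_overlapping, n_discordant]
    for r in deltas:
        r.significant = is_significant(r.delta_svm, thr)
        if r.motif_site is None:
            continue
        for trait in traits.get(r.snv.id, ()):
            cells[trait][0] += 1
            if not r.significant:
                cells[trait][1] += 1
    rows = []
    for trait in all_traits:
        n_overlap, n_disc = cells[trait]
        cell = DiscordanceCell(tf, trait, n_overlap, n_disc)
        pct = cell.percent_discordant
        rows.append(
            {
                "tf": tf,
                "trait": trait,
                "n_overlapping": n_overlap,
                "n_discordant": n_disc,
                "percent_discordant": float("nan") if pct is None else pct,
            }
        )
    return pd.DataFrame(
        rows, columns=["tf", "trait", "n_overlapping", "n_discordant", "percent_discordant"]
    )


def discordance_matrix(long_table: pd.DataFrame) -> pd.DataFrame:
    """Wide TF x trait matrix of discordance percentages (heatmap layout)."""
    return long_table.pivot(index="tf", columns="trait", values="percent_discordant")


def correlation_pwm_vs_svm(
    pwm: PWM,
    table: KmerWeightTable,
    top_n: int = 1000,
    method: str = "pearson",
    log_probability: bool = False,
) -> float:
    """Correlation between PWM match probabilities and SVM weights over the
    ``top_n`` words ranked by PWM score.

    Words are of the table's word length (10-mers in the full-scale setting).
    Returns NaN when either variable has zero variance (undefined
    correlation). ``log_probability`` correlates against log-probabilities
    instead of raw probabilities.
    """
    from scipy import stats

    top = top_scoring_kmers(pwm, table.word_length, top_n)
    x = np.array([p for _, p in top])
    if log_probability:
        x = np.log(np.maximum(x, np.finfo(float).tiny))
    y = np.array([table.weight(kmer) for kmer, _ in top])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def rank_auc_roc(pos_scores, neg_scores) -> float:
    """AUC-ROC via the rank (Mann-Whitney) formulation with tie correction."""
    from sklearn.metrics import roc_auc_score

    pos_scores, neg_scores = np.asarray(pos_scores), np.asarray(neg_scores)
    y = np.r_[np.ones(pos_scores.size), np.zeros(neg_scores.size)]
    return float(roc_auc_score(y, np.r_[pos_scores, neg_scores]))


def _pwm_sequence_score(pwm: PWM, seq: str, summarize: str) -> float | None:
    vals = np.concatenate(
        [window_probabilities(pwm, seq, "+"), window_probabilities(pwm, seq, "-")]
    )
    vals = vals[vals >= 0]  # drop unscorable windows
    if vals.size == 0:
        return None
    return float(vals.max() if summarize == "maximum" else vals.mean())


def roc_prc_comparison(
    pos_seqs: list[str],
    neg_seqs: list[str],
    pwm: PWM,
    table: KmerWeightTable,
    summarize: str = "average",
) -> dict:
    """Compare PWM-probability and SVM-weight scoring of bound vs unbound
    sequences.

    Every sequence is scored by (a) PWM match probability over all motif-
    length windows on both strands and (b) SVM weight over all word-length
    windows, each reduced by ``summarize`` ("average" or "maximum"). Returns
    AUC-ROC (rank formulation) and AUC-PRC (step interpolation) per scorer;
    sequences too short for either model are excluded with a logged count.
    """
    from sklearn.metrics import average_precision_score

    if summarize not in ("average", "maximum"):
        raise ValueError(f"summarize must be 'average' or 'maximum', got {summarize!r}")
    if not pos_seqs or not neg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    scores: dict[str, dict[int, list[float]]] = {"pwm": {0: [], 1: []}, "svm": {0: [], 1: []}}
    n_excluded = 0
    min_len = max(pwm.length, table.word_length)
    for label, seqs in ((1, pos_seqs), (0, neg_seqs)):
        for seq in seqs:
            if len(seq) < min_len:
                n_excluded += 1
                continue
            p = _pwm_sequence_score(pwm, seq, summarize)
            if p is None:
                n_excluded += 1
                continue
            s = sequence_svm_score(table, seq, summarize)
            scores["pwm"][label].append(p)
            scores["svm"][label].append(s)
    if n_excluded:
        logger.info("excluded %d sequence(s) shorter than the models", n_excluded)
    out: dict = {"summarize": summarize, "n_excluded": n_excluded}
    for scorer in ("pwm", "svm"):
        pos, neg = scores[scorer][1], scores[scorer][0]
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        s = np.r_[pos, neg]
        out[scorer] = {
            "auc_roc": rank_auc_roc(pos, neg),
            "auc_prc": float(average_precision_score(y, s)),
        }
    return out
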