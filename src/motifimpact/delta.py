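"""Per-SNV effect scores: deltaSVM and delta-PWM.

deltaSVM of a bi-allelic SNV is the sum, over the l word-windows that contain
the variant base, of (variant-word weight - reference-word weight). Because
the weights of windows not containing the SNV cancel, this equals the
difference of whole-sequence sum-scores between the variant and wild-type
haplotypes — the identity the tests exercise via an independent sliding-
window oracle.

delta-PWM compares the PWM match probability of the wild-type motif sequence
against the variant motif sequence at a PWM-called site (strand-adjusted);
it is only defined when the SNV lies inside a putative site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .alphabet import revcomp
from .gkm import KmerWeightTable
from .io import SnvRecord, fetch
from .pwm import PWM, MotifSite, pwm_probability

logger = logging.getLogger(__name__)

__all__ = ["DeltaResult", "delta_svm", "delta_pwm", "score_snv_set", "results_to_frame"]


class EdgeError(ValueError):
    """SNV too close to a contig edge for full flanking context."""


@dataclass
class DeltaResult:
    """Scores for one SNV; ``delta_pwm``/``motif_site`` are present iff the
    SNV overlaps at least one putative binding site."""

    snv: SnvRecord
    delta_svm: float
    delta_pwm: float | None = None
    motif_site: MotifSite | None = None
    significant: bool | None = None
    all_sites: list[MotifSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_svm):
            raise ValueError("delta_svm must be finite")
        if (self.delta_pwm is None) != (self.motif_site is None):
            raise ValueError("delta_pwm and motif_site must be present together")


def _context(genome, snv: SnvRecord, l: int) -> str:
    """The (2l-1)-base window centred on the SNV, uppercased; verifies ref."""
    chrom_len = len(genome[snv.chrom])
    if snv.pos < l - 1 or snv.pos + l > chrom_len:
        raise EdgeError(
            f"SNV {snv.id} at {snv.chrom}:{snv.pos} lacks {l - 1} bases of flank"
        )
    ctx = fetch(genome, snv.chrom, snv.pos - (l - 1), snv.pos + l).upper()
    if ctx[l - 1] != snv.ref:
        raise ValueError(
            f"reference mismatch for {snv.id}: genome has {ctx[l - 1]}, "
            f"record says {snv.ref}"
        )
    return ctx


def delta_svm(table: KmerWeightTable, genome, snv: SnvRecord) -> float:
    """Sum over the l overlapping word pairs of weight(variant) - weight(WT)."""
    l = table.word_length
    wt = _context(genome, snv, l)
    var = wt[: l - 1] + snv.alt + wt[l:]
    total = 0.0
    for i in range(l):
        total += table.weight(var[i : i + l]) - table.weight(wt[i : i + l])
    return total


def delta_pwm(pwm: PWM, site: MotifSite, genome, snv: SnvRecord, scale: str = "probability") -> float:
    """P(WT motif) - P(variant motif) under the PWM at a called site.

    On the probability scale (default) the value lies in [-1, 1]; positive
    means the variant weakens the match. ``scale="log"`` returns the
    difference of negative-log scores instead (-log P(WT) + log P(variant)),
    which can be infinite when one allele has probability zero.
    """
    if not (site.start <= snv.pos < site.end):
        raise ValueError(
            f"SNV {snv.id} at {snv.chrom}:{snv.pos} outside site "
            f"[{site.start}, {site.end})"
        )
    if snv.chrom != site.chrom:
        raise ValueError("SNV and site on different contigs")
    wt = fetch(genome, site.chrom, site.start, site.end).upper()
    offset = snv.pos - site.start
    if wt[offset] != snv.ref:
        raise ValueError(
            f"reference mismatch for {snv.id}: genome has {wt[offset]}, "
            f"record says {snv.ref}"
        )
    var = wt[:offset] + snv.alt + wt[offset + 1 :]
    if site.strand == "-":
        wt, var = revcomp(wt), revcomp(var)
    p_wt, p_var = pwm_probability(pwm, wt), pwm_probability(pwm, var)
    if scale == "probability":
        return p_wt - p_var
    if scale == "log":
        log_wt = math.inf if p_wt == 0 else -math.log(p_wt)
        log_var = math.inf if p_var == 0 else -math.log(p_var)
        return log_wt - log_var
    raise ValueError(f"unknown scale {scale!r}")


def score_snv_set(
    table: KmerWeightTable,
    pwm: PWM,
    genome,
    snvs: list[SnvRecord],
    sites: list[MotifSite],
    keep_all_overlaps: bool = False,
    pwm_scale: str = "probability",
) -> list[DeltaResult]:
    """deltaSVM for every SNV, plus delta-PWM where the SNV overlaps a
    putative site.

    When a SNV overlaps several sites, delta-PWM is reported for the site
    with the highest wild-type match probability (the strongest annotation);
    all overlapping sites are retained in ``all_sites`` when
    ``keep_all_overlaps``. Edge-case SNVs (insufficient flank) are skipped
    with a logged count. Results are ordered by (chrom, pos).
    """
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s)
    results: list[DeltaResult] = []
    n_skipped = 0
    for snv in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
        try:
            dsvm = delta_svm(table, genome, snv)
        except EdgeError:
            n_skipped += 1
            continue
        tree = trees.get(snv.chrom)
        overlaps = (
            sorted(
                (iv.data for iv in tree[snv.pos]),
                key=lambda s: (-s.probability, s.start, s.strand),
            )
            if tree is not None
            else []
        )
        if overlaps:
            best = overlaps[0]
            dpwm = delta_pwm(pwm, best, genome, snv, scale=pwm_scale)
            results.append(
                DeltaResult(
                    snv=snv,
                    delta_svm=dsvm,
                    delta_pwm=dpwm,
                    motif_site=best,
                    all_sites=overlaps if keep_all_overlaps else [best],
                )
            )
        else:
            results.append(DeltaResult(snv=snv, delta_svm=dsvm))
    if n_skipped:
        logger.info("skipped %d SNV(s) too close to contig edges", n_skipped)
    return results


def results_to_frame(results: list[DeltaResult]) -> pd.DataFrame:
    """Tabular output; positions are reported 1-based."""
    rows = []
    for r in results:
        site = r.motif_site
        rows.append(
            {
                "id": r.snv.id,
                "chrom": r.snv.chrom,
                "pos": r.snv.pos + 1,
                "ref": r.snv.ref,
                "alt": r.snv.alt,
                "delta_svm": r.delta_svm,
                "delta_pwm": r.delta_pwm,
                "motif_id": site.motif_id if site else None,
                "site_start": site.start if site else None,
                "site_end": site.end if site else None,
                "strand": site.strand if site else None,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
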