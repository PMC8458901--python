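"""End-to-end synthetic study: simulate -> train -> weights -> calibrate ->
survey, with the recovery metrics used to validate the whole pipeline.

This is the programmatic counterpart of running the CLI subcommands in
sequence, returning the intermediate objects alongside summary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate, is_significant
from .delta import DeltaResult, score_snv_set
from .gkm import GkmParams, KmerWeightTable
from .model import GkmSvm, GkmSvmResults
from .nulls import sample_matched_nulls
from .pwm import PWM, top_scoring_kmers, scan_genome
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .survey import (
    assign_traits,
    discordance_table,
    expand_ld_window,
    rank_auc_roc,
    select_index_snvs,
)

__all__ = ["PipelineResult", "run_synthetic_pipeline"]


@dataclass
class PipelineResult:
    """Objects and metrics from one synthetic end-to-end run."""

    study: SimulatedStudy
    svm: GkmSvmResults
    table: KmerWeightTable
    calibration: CalibrationResult
    deltas: list[DeltaResult]
    discordance: pd.DataFrame
    metrics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Synthetic pipeline metrics", "=" * 40]
        for key, val in self.metrics.items():
            lines.append(f"{key:<36}{val:.4g}" if isinstance(val, float) else f"{key:<36}{val}")
        return "\n".join(lines)


def run_synthetic_pipeline(
    cfg: SimulationConfig | None = None,
    gkm_params: GkmParams | None = None,
    seed: int = 0,
    heldout_fraction: float = 1 / 3,
    scan_threshold_fraction: float = 1e-3,
    n_control_sites: int = 1000,
    alpha: float = 0.05,
    p_threshold: float = 1e-6,
    ld_window: int = 5000,
) -> PipelineResult:
    """Simulate a study and push it through the full pipeline.

    ``scan_threshold_fraction`` sets the putative-site probability cutoff as
    a fraction of the consensus match probability (the scan threshold is a
    free parameter of any PWM pipeline; anchoring it to the consensus makes
    it transfer across simulated motifs). A ``heldout_fraction`` of the
    peak/null sequences is held out of training to measure generalization.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    gkm_params = gkm_params or GkmParams(word_length=6, informative_positions=4)
    study = simulate_study(cfg)
    genome = study.genome

    # positives = peak sequences, negatives = matched nulls
    from .io import fetch

    pos_seqs = [fetch(genome, c, s, e) for c, s, e in study.peaks]
    # a generous attempt cap: GC-rich motifs can push peak GC several sd
    # from the genome mean, making 0.02-matched windows rare
    _, neg_seqs = sample_matched_nulls(
        genome, study.peaks, seed=cfg.seed + 1, max_attempts=50_000
    )

    rng = np.random.default_rng(cfg.seed + 2)
    n = len(pos_seqs)
    n_test = max(1, int(round(heldout_fraction * n)))
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train_pos = [s for i, s in enumerate(pos_seqs) if i not in test_idx]
    train_neg = [s for i, s in enumerate(neg_seqs) if i not in test_idx]
    test_pos = [pos_seqs[i] for i in sorted(test_idx)]
    test_neg = [neg_seqs[i] for i in sorted(test_idx)]

    svm = GkmSvm(train_pos, train_neg, gkm_params).fit()
    heldout_auc = rank_auc_roc(svm.decision_function(test_pos), svm.decision_function(test_neg))
    table = svm.weight_table()

    # where does the motif's best word rank among all words?
    l = gkm_params.word_length
    consensus_word = top_scoring_kmers(study.pwm, l, 1)[0][0]
    consensus_rank = table.rank_of(consensus_word)
    consensus_rank_percent = 100.0 * consensus_rank / table.weights.size

    scan_threshold = study.pwm.consensus_probability * scan_threshold_fraction
    sites = scan_genome(study.pwm, genome, scan_threshold)

    cal = calibrate(
        table,
        genome,
        study.pwm,
        scan_threshold,
        n_sites=n_control_sites,
        alpha=alpha,
        seed=cfg.seed + 3,
    )

    deltas = score_snv_set(table, study.pwm, genome, study.snvs, sites)
    by_id = {r.snv.id: r for r in deltas}
    label_of = dict(zip(study.truth["id"], study.truth["label"]))
    sig_fraction = {}
    for label in ("motif_conserved", "motif_degenerate", "background"):
        ids = [i for i, lab in label_of.items() if lab == label and i in by_id]
        if ids:
            sig_fraction[label] = float(
                np.mean([is_significant(by_id[i].delta_svm, cal.thresholds) for i in ids])
            )

    index = select_index_snvs(study.associations, p_threshold)
    candidates = expand_ld_window(index, study.snvs, ld_window)
    traits = assign_traits(index, candidates, ld_window)
    cand_deltas = [by_id[s.id] for s in candidates if s.id in by_id]
    disc = discordance_table(cand_deltas, cal.thresholds, traits, tf=study.pwm.motif_id)

    n_overlap = int(disc["n_overlapping"].sum())
    n_disc = int(disc["n_discordant"].sum())
    metrics = {
        "heldout_roc_auc": heldout_auc,
        "consensus_word": consensus_word,
        "consensus_rank_percent": consensus_rank_percent,
        "threshold_lower": cal.thresholds.lower,
        "threshold_upper": cal.thresholds.upper,
        "significant_fraction_conserved": sig_fraction.get("motif_conserved", float("nan")),
        "significant_fraction_degenerate": sig_fraction.get("motif_degenerate", float("nan")),
        "significant_fraction_background": sig_fraction.get("background", float("nan")),
        "n_candidate_snvs": len(candidates),
        "n_overlapping_snvs": n_overlap,
        "discordant_percent": (100.0 * n_disc / n_overlap) if n_overlap else float("nan"),
        "n_sites_called": len(sites),
    }
    return PipelineResult(
        study=study,
        svm=svm,
        table=table,
        calibration=cal,
        deltas=deltas,
        discordance=disc,
        metrics=metrics,
    )
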