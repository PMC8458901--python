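"""Synthetic study generator with known ground truth.

Emulates the inputs a real SNV/TF-binding survey needs — a soft-masked
genome, a TF motif with conserved and degenerate positions, ChIP-seq-style
peaks enriched for motif instances, a panel of SNVs planted at conserved vs
degenerate motif positions plus background positions, and a variant-trait
association table with index SNVs — so every pipeline stage can be exercised
and validated without any external download. Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import BASES, revcomp
from .io import (
    Interval,
    SnvRecord,
    write_associations,
    write_bed,
    write_fasta,
    write_snvs_vcf,
)
from .pwm import PWM, write_pwm

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_pwm",
    "simulate_peaks",
    "simulate_snvs",
    "simulate_associations",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters (defaults are the desk-scale conditions
    the package is validated under; see docs/methods.md).

    genome_length : bp of the single synthetic contig.
    gc_content : genome-wide GC fraction (0.45; regulatory-region-like,
        slightly above the genomic average).
    repeat_tracts_per_kb / repeat_tract_mean_length : density and mean
        (geometric) length of soft-masked tracts.
    pwm_length / n_conserved_positions : motif size and how many positions
        carry a dominant base; conserved dominant-base probability is drawn
        uniformly from [conserved_min_prob, conserved_max_prob], degenerate
        columns are near-uniform Dirichlet.
    n_peaks / peak_length / motif_planting_rate : ChIP-seq-style peak set;
        each peak receives ``motif_planting_rate`` motif instances sampled
        from the PWM (not the consensus, so weight learning sees realistic
        degeneracy).
    n_background_snvs / n_motif_snvs : SNV panel sizes; motif SNVs are split
        evenly between conserved and degenerate positions of planted
        instances.
    n_traits / n_index_snvs : synthetic association table shape.
    seed : mandatory; all randomness derives from it.
    """

    seed: int
    genome_length: int = 100_000
    gc_content: float = 0.45
    repeat_tracts_per_kb: float = 0.2
    repeat_tract_mean_length: int = 150
    pwm_length: int = 12
    n_conserved_positions: int = 8
    conserved_min_prob: float = 0.92
    conserved_max_prob: float = 0.98
    degenerate_concentration: float = 8.0
    n_peaks: int = 60
    peak_length: int = 150
    motif_planting_rate: int = 3
    n_background_snvs: int = 120
    n_motif_snvs: int = 120
    n_traits: int = 3
    n_index_snvs: int = 6
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_conserved_positions > self.pwm_length:
            raise ValueError("n_conserved_positions exceeds pwm_length")
        counts = (
            self.genome_length,
            self.n_peaks,
            self.peak_length,
            self.motif_planting_rate,
            self.n_background_snvs,
            self.n_motif_snvs,
            self.n_traits,
            self.n_index_snvs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per generator stage so stages stay reproducible
    # even when composed differently
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_genome(cfg: SimulationConfig) -> dict[str, str]:
    """I.i.d. bases at the target GC with lowercase (soft-masked) repeat
    tracts placed at the configured density."""
    rng = _rng(cfg, 0)
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    digits = rng.choice(4, size=cfg.genome_length, p=p)
    seq = np.frombuffer("ACGT".encode(), dtype=np.uint8)[digits]
    mask = np.zeros(cfg.genome_length, dtype=bool)
    n_tracts = rng.poisson(cfg.repeat_tracts_per_kb * cfg.genome_length / 1000)
    for _ in range(n_tracts):
        length = int(rng.geometric(1.0 / cfg.repeat_tract_mean_length))
        start = int(rng.integers(0, max(1, cfg.genome_length - length)))
        mask[start : start + length] = True
    chars = seq.view("S1").astype("U1")
    chars[mask] = np.char.lower(chars[mask])
    return {cfg.chrom_name: "".join(chars)}


def simulate_pwm(cfg: SimulationConfig) -> tuple[PWM, list[str]]:
    """A motif with labelled conserved (dominant base probability >= 0.9) and
    degenerate (near-uniform) positions. Returns (pwm, label map)."""
    rng = _rng(cfg, 1)
    L = cfg.pwm_length
    conserved = set(
        rng.choice(L, size=cfg.n_conserved_positions, replace=False).tolist()
    )
    probs = np.empty((L, 4))
    labels = []
    for i in range(L):
        if i in conserved:
            dominant = int(rng.integers(4))
            p_dom = float(rng.uniform(cfg.conserved_min_prob, cfg.conserved_max_prob))
            rest = rng.dirichlet(np.ones(3)) * (1 - p_dom)
            row = np.insert(rest, dominant, p_dom)
            labels.append("conserved")
        else:
            row = rng.dirichlet(np.full(4, cfg.degenerate_concentration))
            labels.append("degenerate")
        probs[i] = row
    return PWM(probs, motif_id="sim_motif"), labels


def simulate_peaks(
    genome: dict[str, str], pwm: PWM, cfg: SimulationConfig
) -> tuple[dict[str, str], list[Interval], pd.DataFrame]:
    """Place non-overlapping peaks (avoiding soft-masked tracts) and plant
    ``motif_planting_rate`` PWM-sampled instances in each.

    Returns the genome with instances written in, the peak intervals, and the
    planting record (chrom, start, end, strand, peak index) as ground truth.
    """
    rng = _rng(cfg, 2)
    chrom = cfg.chrom_name
    seq = list(genome[chrom])
    n = len(seq)
    L = cfg.peak_length
    peaks: list[Interval] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(peaks) < cfg.n_peaks:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                f"could not place {cfg.n_peaks} non-overlapping peaks of {L} bp "
                f"in {n} bp of genome"
            )
        start = int(rng.integers(0, n - L + 1))
        end = start + L
        if any(s < end and start < e for s, e in occupied):
            continue
        if any(c.islower() for c in seq[start:end]):
            continue
        occupied.append((start, end))
        peaks.append((chrom, start, end))
    peaks.sort(key=lambda p: p[1])

    records = []
    M = pwm.length
    for peak_index, (_, pstart, pend) in enumerate(peaks):
        planted: list[tuple[int, int]] = []
        for _ in range(cfg.motif_planting_rate):
            for _ in range(10_000):
                off = int(rng.integers(0, cfg.peak_length - M + 1))
                if all(off + M <= s or e <= off for s, e in planted):
                    planted.append((off, off + M))
                    break
            else:
                raise RuntimeError("could not place motif instances within a peak")
            digits = [int(rng.choice(4, p=pwm.probs[i])) for i in range(M)]
            instance = "".join(BASES[d] for d in digits)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = instance if strand == "+" else revcomp(instance)
            gstart = pstart + off
            seq[gstart : gstart + M] = list(inserted)
            records.append(
                {
                    "chrom": chrom,
                    "start": gstart,
                    "end": gstart + M,
                    "strand": strand,
                    "peak_index": peak_index,
                }
            )
    planting = pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "peak_index"]
    ).sort_values("start", ignore_index=True)
    return {chrom: "".join(seq)}, peaks, planting


def simulate_snvs(
    genome: dict[str, str],
    planting: pd.DataFrame,
    labels: list[str],
    cfg: SimulationConfig,
) -> tuple[list[SnvRecord], pd.DataFrame]:
    """SNV panel: background SNVs at uniform non-motif positions plus motif
    SNVs split between conserved and degenerate positions of planted
    instances.

    The truth table labels each SNV {background, motif_conserved,
    motif_degenerate}; reference alleles always match the genome.
    """
    rng = _rng(cfg, 3)
    chrom = cfg.chrom_name
    seq = genome[chrom]
    n = len(seq)

    motif_positions: dict[str, list[int]] = {"conserved": [], "degenerate": []}
    in_motif = set()
    for row in planting.itertuples():
        for gpos in range(row.start, row.end):
            in_motif.add(gpos)
            offset = gpos - row.start
            motif_idx = offset if row.strand == "+" else (row.end - row.start - 1 - offset)
            motif_positions[labels[motif_idx]].append(gpos)

    def _draw_alt(ref: str) -> str:
        choices = [b for b in BASES if b != ref]
        return choices[int(rng.integers(3))]

    snvs: list[SnvRecord] = []
    truth_rows = []
    counter = 0

    def _add(pos: int, label: str) -> None:
        nonlocal counter
        ref = seq[pos].upper()
        if ref not in BASES:
            return
        counter += 1
        snv = SnvRecord(chrom=chrom, pos=pos, ref=ref, alt=_draw_alt(ref), id=f"snv{counter:05d}")
        snvs.append(snv)
        truth_rows.append(
            {"id": snv.id, "chrom": chrom, "pos": pos, "ref": snv.ref, "alt": snv.alt, "label": label}
        )

    n_conserved_snvs = cfg.n_motif_snvs // 2
    n_degenerate_snvs = cfg.n_motif_snvs - n_conserved_snvs
    for label, count in (("conserved", n_conserved_snvs), ("degenerate", n_degenerate_snvs)):
        pool = sorted(set(motif_positions[label]))
        if count > len(pool):
            raise ValueError(
                f"requested {count} {label}-position SNVs but only {len(pool)} "
                "planted positions are available"
            )
        for pos in rng.choice(len(pool), size=count, replace=False):
            _add(pool[int(pos)], f"motif_{label}")

    background_pool = np.array(sorted(set(range(n)) - in_motif))
    chosen = rng.choice(background_pool.size, size=cfg.n_background_snvs, replace=False)
    for i in chosen:
        _add(int(background_pool[i]), "background")

    order = np.argsort([s.pos for s in snvs], kind="stable")
    snvs = [snvs[i] for i in order]
    truth = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    return snvs, truth


def simulate_associations(
    snvs: list[SnvRecord], truth: pd.DataFrame, cfg: SimulationConfig
) -> pd.DataFrame:
    """Designate index SNVs with genome-wide-significant p-values (< 1e-6)
    for synthetic traits; all other SNVs get clearly non-significant
    p-values. Index SNVs are drawn from the background set so that the LD
    windows around them, not the index variants themselves, carry the
    motif-disrupting signal."""
    rng = _rng(cfg, 4)
    background_ids = [s.id for s in snvs if truth.set_index("id").loc[s.id, "label"] == "background"]
    n_index = min(cfg.n_index_snvs, len(background_ids))
    index_ids = set(
        np.array(background_ids)[rng.choice(len(background_ids), size=n_index, replace=False)]
    )
    traits = [f"trait_{chr(ord('A') + i)}" for i in range(cfg.n_traits)]
    rows = []
    trait_cycle = 0
    for snv in snvs:
        if snv.id in index_ids:
            trait = traits[trait_cycle % len(traits)] if traits else "trait_A"
            trait_cycle += 1
            p = 10.0 ** rng.uniform(-9, -7)
        else:
            trait = traits[int(rng.integers(len(traits)))] if traits else "trait_A"
            p = 10.0 ** rng.uniform(-5, -2)
        rows.append(
            {"snv_id": snv.id, "chrom": snv.chrom, "pos": snv.pos, "p_value": p, "trait": trait}
        )
    return pd.DataFrame(rows, columns=["snv_id", "chrom", "pos", "p_value", "trait"])


@dataclass
class SimulatedStudy:
    """Everything one synthetic study comprises, with ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    pwm: PWM
    position_labels: list[str]
    peaks: list[Interval]
    planting: pd.DataFrame
    snvs: list[SnvRecord]
    truth: pd.DataFrame
    associations: pd.DataFrame


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run all generators in order; pure function of the config (incl. seed)."""
    genome = simulate_genome(cfg)
    pwm, labels = simulate_pwm(cfg)
    genome, peaks, planting = simulate_peaks(genome, pwm, cfg)
    snvs, truth = simulate_snvs(genome, planting, labels, cfg)
    associations = simulate_associations(snvs, truth, cfg)
    return SimulatedStudy(
        config=cfg,
        genome=genome,
        pwm=pwm,
        position_labels=labels,
        peaks=peaks,
        planting=planting,
        snvs=snvs,
        truth=truth,
        associations=associations,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Emit genome.fa, peaks.bed, motif.pwm, snvs.vcf, truth.tsv,
    associations.tsv and config.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, outdir / "genome.fa")
    write_bed(study.peaks, outdir / "peaks.bed")
    write_pwm(study.pwm, outdir / "motif.pwm")
    write_snvs_vcf(
        study.snvs,
        outdir / "snvs.vcf",
        contigs={c: len(s) for c, s in study.genome.items()},
    )
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_associations(study.associations, outdir / "associations.tsv")
    with open(outdir / "config.json", "w") as fh:
        payload = asdict(study.config)
        payload["position_labels"] = study.position_labels
        json.dump(payload, fh, indent=2)
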