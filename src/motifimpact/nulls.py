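"""Matched null sequences and random non-motif control sites.

Negative training sequences are drawn from outside the peak set, rejection-
sampled so each null matches one positive region in GC fraction, repeat
fraction (fraction of soft-masked, i.e. lowercase, bases) and length within
configurable tolerances (all default 0.02, per the genNullSeqs convention).
Non-motif sites — the raw material of the empirical deltaSVM null — are
uniform windows whose PWM match probability on both strands stays below the
scan threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io import Interval, contig_lengths, fetch
from .pwm import PWM, window_probabilities

__all__ = [
    "MatchTolerances",
    "gc_fraction",
    "repeat_fraction",
    "sample_matched_nulls",
    "sample_non_motif_sites",
]


@dataclass(frozen=True)
class MatchTolerances:
    """Maximum allowed positive-vs-null differences: absolute in GC fraction
    and repeat fraction, relative in length."""

    gc: float = 0.02
    repeat: float = 0.02
    length: float = 0.02

    def __post_init__(self) -> None:
        if min(self.gc, self.repeat, self.length) < 0:
            raise ValueError("tolerances must be >= 0")


def gc_fraction(seq: str) -> float:
    """G+C fraction (case-insensitive) among all bases."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(seq)


def repeat_fraction(seq: str) -> float:
    """Fraction of soft-masked (lowercase) bases."""
    if not seq:
        return 0.0
    return sum(c.islower() for c in seq) / len(seq)


def _trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def sample_matched_nulls(
    genome,
    peaks: list[Interval],
    n: int | None = None,
    tol: MatchTolerances | None = None,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> tuple[list[Interval], list[str]]:
    """Sample one matched non-peak interval per positive region.

    For each positive (the peak list itself by default; sampled with
    replacement when ``n`` exceeds its length), draws uniform intervals of the
    same length until one satisfies the GC/repeat tolerances and overlaps
    neither a peak nor a previously accepted null. Pure function of
    (inputs, seed).

    Returns ``(intervals, sequences)`` in positive order.

    Raises
    ------
    RuntimeError
        If no match is found within ``max_attempts`` draws for some positive
        (names the unmatched positive).
    """
    tol = tol or MatchTolerances()
    rng = np.random.default_rng(seed)
    if not peaks:
        raise ValueError("peak set is empty")
    sizes = contig_lengths(genome)
    chroms = list(sizes)
    chrom_weights = np.array([sizes[c] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()
    occupied = _trees(peaks)

    if n is None:
        positives = list(peaks)
    else:
        idx = rng.integers(0, len(peaks), size=n)
        positives = [peaks[i] for i in idx]

    intervals: list[Interval] = []
    seqs: list[str] = []
    for chrom0, start0, end0 in positives:
        pos_seq = fetch(genome, chrom0, start0, end0)
        gc0, rep0, L0 = gc_fraction(pos_seq), repeat_fraction(pos_seq), end0 - start0
        # lengths are kept identical to the positive; the relative-length
        # tolerance is then satisfied with difference zero
        for _ in range(max_attempts):
            chrom = chroms[rng.choice(len(chroms), p=chrom_weights)]
            if sizes[chrom] < L0:
                continue
            start = int(rng.integers(0, sizes[chrom] - L0 + 1))
            end = start + L0
            tree = occupied.get(chrom)
            if tree is not None and tree.overlaps(start, end):
                continue
            seq = fetch(genome, chrom, start, end)
            if abs(gc_fraction(seq) - gc0) > tol.gc:
                continue
            if abs(repeat_fraction(seq) - rep0) > tol.repeat:
                continue
            occupied.setdefault(chrom, IntervalTree()).addi(start, end)
            intervals.append((chrom, start, end))
            seqs.append(seq)
            break
        else:
            raise RuntimeError(
                f"no matched null found for positive {chrom0}:{start0}-{end0} "
                f"within {max_attempts} attempts (gc={gc0:.3f}, repeat={rep0:.3f})"
            )
    return intervals, seqs


def sample_non_motif_sites(
    genome,
    pwm: PWM,
    threshold: float,
    n: int,
    seed: int | None = None,
    exclude: list[Interval] | None = None,
    disjoint: bool = False,
    max_draws: int = 1_000_000,
) -> list[Interval]:
    """Uniformly sample length-L windows whose PWM probability stays below
    ``threshold`` on both strands.

    Sites may overlap one another unless ``disjoint``; ``exclude`` removes
    windows intersecting the given intervals (e.g. peaks). Pure function of
    (inputs, seed).

    Raises
    ------
    RuntimeError
        If the acceptance rate falls below 1e-4 after ``max_draws`` draws,
        which suggests the threshold admits almost every window as a motif.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    rng = np.random.default_rng(seed)
    L = pwm.length
    sizes = contig_lengths(genome)
    chroms = [c for c in sizes if sizes[c] >= L]
    if not chroms:
        raise ValueError("no contig long enough for the motif")
    weights = np.array([sizes[c] - L + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    excl = _trees(exclude) if exclude else {}
    taken: dict[str, IntervalTree] = {}

    accepted: list[Interval] = []
    draws = 0
    while len(accepted) < n:
        if draws >= max_draws:
            rate = len(accepted) / draws
            if rate < 1e-4:
                raise RuntimeError(
                    f"non-motif site acceptance rate {rate:.2e} after {draws} draws; "
                    "review the scan threshold"
                )
        draws += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, sizes[chrom] - L + 1))
        end = start + L
        tree = excl.get(chrom)
        if tree is not None and tree.overlaps(start, end):
            continue
        if disjoint:
            tree = taken.get(chrom)
            if tree is not None and tree.overlaps(start, end):
                continue
        seq = fetch(genome, chrom, start, end)
        fwd = window_probabilities(pwm, seq, "+")
        rev = window_probabilities(pwm, seq, "-")
        if fwd.size == 0 or fwd[0] < 0:  # unscorable (non-ACGT) window
            continue
        if max(fwd[0], rev[0]) >= threshold:
            continue
        if disjoint:
            taken.setdefault(chrom, IntervalTree()).addi(start, end)
        accepted.append((chrom, start, end))
    return accepted
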