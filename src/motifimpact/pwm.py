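"""Position weight matrix (PWM) models of transcription factor binding motifs.

A PWM is a product-multinomial (order-zero inhomogeneous Markov) model: column
``i`` holds the probability of each nucleotide at motif position ``i``. The
match probability of an L-mer is the product of the per-position probabilities,
and the classical motif score is its negative log. Internally everything is
ranked on the probability scale ("top" = highest probability), which keeps the
familiar "highest score = best match" ordering unambiguous; ``pwm_score`` is a
reporting convenience.

Shorter words (e.g. 10-mers against a 15-bp motif) are scored by sliding the
word along the motif columns and taking the best of the ``L - w + 1``
alignments; when the motif length equals the word length there is a single
alignment and the score reduces to the full match probability.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    BASES,
    all_codes,
    code_to_kmer,
    codes_to_digits,
    encode,
    require_acgt,
    revcomp,
)

__all__ = [
    "PWM",
    "MotifSite",
    "parse_pwm",
    "read_pwm",
    "write_pwm",
    "pwm_probability",
    "pwm_score",
    "max_window_probability",
    "relative_entropy",
    "scan_sequence",
    "scan_genome",
    "top_scoring_kmers",
    "window_probabilities",
    "write_sites_bed",
    "read_sites_bed",
]


@dataclass
class PWM:
    """Per-position nucleotide probability matrix over the alphabet ACGT.

    Parameters
    ----------
    probs : (L, 4) array
        Row ``i`` holds the probabilities of A, C, G, T at motif position
        ``i``. Rows are renormalized to sum to one exactly.
    motif_id : str
        Label carried into scan output.
    background : (4,) array
        Background nucleotide probabilities; the conventional flat 0.25 by
        default.
    """

    probs: np.ndarray
    motif_id: str = "motif"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PWM matrix must be (L, 4); got shape {probs.shape}")
        if (probs < 0).any():
            bad = int(np.argwhere(probs < 0)[0][0])
            raise ValueError(f"negative probability in PWM row {bad}")
        sums = probs.sum(axis=1)
        if (sums <= 0).any():
            bad = int(np.argmax(sums <= 0))
            raise ValueError(f"PWM row {bad} sums to zero")
        self.probs = probs / sums[:, None]
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or bg.sum() <= 0:
            raise ValueError("background must be a nonnegative 4-vector")
        self.background = bg / bg.sum()

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-probability base per position (ties broken alphabetically)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def consensus_probability(self) -> float:
        return float(self.probs.max(axis=1).prod())

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.motif_id, self.background[::-1].copy())

    def information_content(self) -> np.ndarray:
        """Per-position relative entropy vs background, in nats."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log(self.probs / self.background)
        return np.where(self.probs > 0, terms, 0.0).sum(axis=1)


@dataclass(frozen=True)
class MotifSite:
    """A putative binding site: an interval whose PWM match probability
    exceeded the scan threshold. Coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    probability: float
    motif_id: str = "motif"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")


def _parse_numeric_rows(text: str) -> tuple[list[list[float]], str | None]:
    """Parse whitespace/bracket-delimited numeric rows, tolerating A/C/G/T row
    labels. Returns (rows, motif_id from a '>' header if present)."""
    motif_id = None
    rows: list[list[float]] = []
    labels: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if line[1:].split() else None
            continue
        line = line.replace("[", " ").replace("]", " ")
        fields = line.replace(":", " ").split()
        if fields and re.fullmatch(r"[ACGTacgt]", fields[0]):
            labels.append(fields[0].upper())
            fields = fields[1:]
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ValueError(f"malformed PWM row at line {lineno}: {raw!r}") from exc
    if labels and len(labels) == len(rows) and sorted(labels) == list("ACGT"):
        # reorder labelled rows to A, C, G, T
        order = [labels.index(b) for b in BASES]
        rows = [rows[i] for i in order]
    return rows, motif_id


def _parse_jaspar(text: str) -> tuple[np.ndarray, str | None] | None:
    """Parse header + labelled-row JASPAR text via Bio.motifs; returns the
    (L, 4) matrix in ACGT column order, or None if biopython rejects it."""
    from Bio import motifs as bio_motifs

    try:
        motif = bio_motifs.read(_io.StringIO(text), "jaspar")
    except Exception:
        return None
    mat = np.array([motif.counts[b] for b in BASES], dtype=float).T
    name = getattr(motif, "matrix_id", None) or motif.name
    return mat, name


def parse_pwm(
    text: str,
    fmt: str = "auto",
    pseudocount: float = 0.25,
    orientation: str = "auto",
    motif_id: str | None = None,
) -> PWM:
    """Parse a JASPAR-style or plain tabular matrix into a :class:`PWM`.

    Counts/frequency matrices (rows not summing to one) are converted to
    probabilities with an additive per-cell ``pseudocount``; matrices already
    in probability form are returned unchanged (no pseudocount applied).

    Parameters
    ----------
    fmt : {"auto", "jaspar", "tabular"}
        Both formats reduce to a labelled or unlabelled numeric matrix; the
        distinction is cosmetic and "auto" accepts either.
    orientation : {"auto", "bases-in-rows", "bases-in-columns"}
        A 4-row matrix is read as bases-in-rows (4 x L), an L x 4 matrix as
        bases-in-columns; 4 x 4 matrices default to bases-in-rows and can be
        overridden here.
    """
    if fmt not in ("auto", "jaspar", "tabular"):
        raise ValueError(f"unknown PWM format {fmt!r}")
    if fmt == "jaspar" or (fmt == "auto" and text.lstrip().startswith(">")):
        parsed = _parse_jaspar(text)
        if parsed is not None:
            mat, header_id = parsed
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                mat = mat + pseudocount
            return PWM(mat, motif_id=motif_id or header_id or "motif")
        if fmt == "jaspar":
            raise ValueError("could not parse JASPAR motif text")
    rows, header_id = _parse_numeric_rows(text)
    if not rows:
        raise ValueError("no numeric rows found in PWM text")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ValueError(
            f"inconsistent PWM row lengths: row {bad} has {len(rows[bad])} "
            f"entries, row 0 has {len(rows[0])}"
        )
    mat = np.asarray(rows, dtype=float)
    if (mat < 0).any():
        bad = int(np.argwhere(mat < 0)[0][0])
        raise ValueError(f"negative entry in PWM row {bad}")

    if orientation == "bases-in-rows":
        bases_in_rows = True
    elif orientation == "bases-in-columns":
        bases_in_rows = False
    else:
        if mat.shape[0] == 4:
            bases_in_rows = True
        elif mat.shape[1] == 4:
            bases_in_rows = False
        else:
            raise ValueError(f"cannot orient PWM matrix of shape {mat.shape}")
    if bases_in_rows:
        mat = mat.T
    if mat.shape[1] != 4:
        raise ValueError(f"PWM matrix must have a dimension of size 4; got {mat.shape}")

    sums = mat.sum(axis=1)
    is_probability = np.allclose(sums, 1.0, atol=1e-6)
    if not is_probability:
        mat = mat + pseudocount
    name = motif_id or header_id or "motif"
    return PWM(mat, motif_id=name)


def read_pwm(path, **kwargs) -> PWM:
    with open(path) as fh:
        return parse_pwm(fh.read(), **kwargs)


def write_pwm(pwm: PWM, path) -> None:
    """Write in labelled JASPAR-like probability form."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id}\n")
        for j, base in enumerate(BASES):
            vals = " ".join(f"{v:.10g}" for v in pwm.probs[:, j])
            fh.write(f"{base} [ {vals} ]\n")


def pwm_probability(pwm: PWM, seq: str) -> float:
    """Match probability of a full-length sequence: the product-multinomial
    likelihood prod_i p[i, s_i]."""
    digits = require_acgt(seq.upper())
    if len(digits) != pwm.length:
        raise ValueError(f"sequence length {len(digits)} != motif length {pwm.length}")
    return float(pwm.probs[np.arange(pwm.length), digits].prod())


def pwm_score(pwm: PWM, seq: str) -> float:
    """Negative natural log of the match probability (the classical motif
    score; lower = better match). Zero probability yields ``inf``."""
    p = pwm_probability(pwm, seq)
    return math.inf if p == 0.0 else -math.log(p)


def max_window_probability(pwm: PWM, word: str) -> float:
    """Best match probability of ``word`` over all contiguous alignments of
    the word to the motif columns (the 10-mer scoring rule; a motif of length
    L offers L - w + 1 alignments, one when L == w)."""
    digits = require_acgt(word.upper())
    w = len(digits)
    if pwm.length < w:
        raise ValueError(
            f"motif length {pwm.length} < word length {w}: unsupported motif"
        )
    idx = np.arange(w)
    best = 0.0
    for offset in range(pwm.length - w + 1):
        best = max(best, float(pwm.probs[offset + idx, digits].prod()))
    return best


def relative_entropy(pwm: PWM, seq: str, negate: bool = False, base: float | None = None) -> float:
    """Relative entropy of a sequence under the PWM vs background:
    sum_i p[i, a_i] * log(p[i, a_i] / bg[a_i]), with 0 log 0 = 0.

    Higher values indicate better fit to the motif model. ``negate`` flips the
    sign convention; ``base`` changes the logarithm base (natural by default).
    """
    digits = require_acgt(seq.upper())
    if len(digits) != pwm.length:
        raise ValueError(f"sequence length {len(digits)} != motif length {pwm.length}")
    p = pwm.probs[np.arange(pwm.length), digits]
    bg = pwm.background[digits]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / bg)
    value = float(np.where(p > 0, terms, 0.0).sum())
    if base is not None:
        value /= math.log(base)
    return -value if negate else value


def window_probabilities(pwm: PWM, seq: str, strand: str = "+") -> np.ndarray:
    """Match probability of every length-L window of ``seq`` on one strand.

    Windows containing non-ACGT characters get the sentinel -1.0. On the minus
    strand the value is the probability of the reverse-complemented window,
    computed via the reverse-complement PWM on the forward coordinates.
    """
    L = pwm.length
    digits = encode(seq)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(digits, L)
    valid = (win != 255).all(axis=1)
    probs = pwm.probs if strand == "+" else pwm.reverse_complement().probs
    safe = np.where(win == 255, 0, win)
    vals = probs[np.arange(L)[None, :], safe].prod(axis=1)
    vals[~valid] = -1.0
    return vals


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold: float,
    strands: str = "both",
    chrom: str = "seq",
) -> list[MotifSite]:
    """Call putative binding sites: every window whose match probability is at
    least ``threshold`` on the requested strand(s).

    Overlapping calls are retained; output is sorted by start then strand
    (+ before -). Windows containing non-ACGT characters are skipped.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    which = "+-" if strands == "both" else strands
    sites = []
    for strand in which:
        vals = window_probabilities(pwm, seq, strand)
        for start in np.flatnonzero(vals >= threshold):
            sites.append(
                MotifSite(
                    chrom=chrom,
                    start=int(start),
                    end=int(start) + pwm.length,
                    strand=strand,
                    probability=float(min(vals[start], 1.0)),
                    motif_id=pwm.motif_id,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def scan_genome(pwm: PWM, genome, threshold: float, strands: str = "both") -> list[MotifSite]:
    """Scan every contig of a genome mapping/FASTA; see :func:`scan_sequence`."""
    sites = []
    for chrom in genome.keys():
        sites.extend(scan_sequence(pwm, str(genome[chrom][:]), threshold, strands, chrom=chrom))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def top_scoring_kmers(pwm: PWM, word_length: int = 10, n: int = 1000) -> list[tuple[str, float]]:
    """The ``n`` words of ``word_length`` with the highest best-alignment match
    probability, out of the exhaustive 4^w enumeration.

    Ties are broken lexicographically so output is deterministic.
    """
    w = word_length
    if pwm.length < w:
        raise ValueError(f"motif length {pwm.length} < word length {w}")
    if n > 4**w:
        raise ValueError(f"n={n} exceeds 4^{w}")
    codes = all_codes(w)
    digits = codes_to_digits(codes, w)
    best = np.zeros(4**w)
    cols = np.arange(w)
    for offset in range(pwm.length - w + 1):
        vals = np.ones(4**w)
        probs = pwm.probs
        for j in range(w):
            vals *= probs[offset + j][digits[:, j]]
        np.maximum(best, vals, out=best)
    order = np.lexsort((codes, -best))[:n]
    return [(code_to_kmer(int(codes[i]), w), float(best[i])) for i in order]


def write_sites_bed(sites: list[MotifSite], path) -> None:
    """6-column BED: chrom, start, end, motif_id, round(1000 * probability), strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.motif_id}\t"
                f"{round(1000 * s.probability)}\t{s.strand}\n"
            )


def read_sites_bed(path, motif_id: str | None = None) -> list[MotifSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                MotifSite(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                    probability=min(int(f[4]) / 1000.0, 1.0) if len(f) > 4 else 1.0,
                    motif_id=motif_id or (f[3] if len(f) > 3 else "motif"),
                )
            )
    return sites
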