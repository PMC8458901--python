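"""Gapped k-mer string kernel and k-mer weight tables.

A sequence is represented by the multiset of gapped words obtained by taking
every length-``l`` window and every choice of ``k`` of its ``l`` positions
(the "informative" positions); the remaining ``l - k`` positions are gaps.
The kernel between two sequences is the inner product of these feature
vectors. For two single l-mers differing at ``m`` positions the inner product
has the closed form C(l - m, k) — a gapped word matches iff its mask avoids
every mismatch — so the kernel between sequences reduces to summing
C(l - hamming, k) over all window pairs, which is what the implementation
does (on bit-packed window codes; no feature vector is ever materialized).

The trained SVM's weight for an individual l-mer ("SVM weight") is the
decision-function contribution of that word; a sequence's SVM score is the
sum (or mean/max) of its windows' weights.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd

from .alphabet import (
    all_codes,
    code_to_kmer,
    hamming_codes,
    kmer_to_code,
    revcomp_codes,
    window_codes,
)

__all__ = [
    "GkmParams",
    "gapped_kmer_features",
    "kernel_mismatch_value",
    "gkm_kernel",
    "gkm_kernel_matrix",
    "KmerWeightTable",
    "sequence_svm_score",
    "topk_weight_overlap",
    "read_weight_table",
    "write_weight_table",
]

ENUMERATION_MAX_L = 12


@dataclass(frozen=True)
class GkmParams:
    """Gapped k-mer kernel/SVM hyperparameters.

    word_length : l, the full k-mer length (default 10).
    informative_positions : k <= l, positions retained per gapped word
        (default 6, the convention of the gkm-SVM family).
    svm_cost : soft-margin C.
    collapse_revcomp : share one weight between each word and its reverse
        complement in weight tables (TF ChIP-seq signal is strand-symmetric).
    normalize_kernel : use K'(a,b) = K(a,b)/sqrt(K(a,a) K(b,b)).
    """

    word_length: int = 10
    informative_positions: int = 6
    svm_cost: float = 1.0
    collapse_revcomp: bool = True
    normalize_kernel: bool = True

    def __post_init__(self) -> None:
        l, k = self.word_length, self.informative_positions
        if not (1 <= k <= l <= ENUMERATION_MAX_L):
            raise ValueError(
                f"require 1 <= k <= l <= {ENUMERATION_MAX_L}; got l={l}, k={k}"
            )
        if self.svm_cost <= 0:
            raise ValueError(f"svm_cost must be positive, got {self.svm_cost}")


def gapped_kmer_features(seq: str, params: GkmParams) -> Counter:
    """Explicit gapped-word multiset of a sequence: for every l-window and
    every k-subset of positions, the feature (position mask, retained
    letters). Quadratic-in-everything; intended for small inputs and as the
    ground truth the fast kernel is checked against."""
    l, k = params.word_length, params.informative_positions
    seq = seq.upper()
    feats: Counter = Counter()
    masks = list(combinations(range(l), k))
    for start in range(len(seq) - l + 1):
        window = seq[start : start + l]
        if any(c not in "ACGT" for c in window):
            continue
        for mask in masks:
            feats[(mask, "".join(window[i] for i in mask))] += 1
    return feats


def kernel_mismatch_value(l: int, k: int, m: int) -> int:
    """Inner product of two single l-mers with m mismatches: C(l - m, k)."""
    return comb(l - m, k) if l - m >= k else 0


def _comb_table(l: int, k: int) -> np.ndarray:
    # index by number of matching positions (l - hamming)
    return np.array([comb(n, k) if n >= k else 0 for n in range(l + 1)], dtype=np.int64)


def _windows(seq: str, l: int) -> np.ndarray:
    codes, valid = window_codes(seq, l)
    return codes[valid]


def gkm_kernel(seq_a: str, seq_b: str, params: GkmParams) -> float:
    """Gapped k-mer inner product of two sequences (raw, unnormalized)."""
    l, k = params.word_length, params.informative_positions
    wa, wb = _windows(seq_a, l), _windows(seq_b, l)
    if wa.size == 0 or wb.size == 0:
        return 0.0
    ham = hamming_codes(wa[:, None], wb[None, :], l)
    return float(_comb_table(l, k)[l - ham].sum())


def gkm_kernel_matrix(
    seqs_a: list[str],
    seqs_b: list[str] | None = None,
    params: GkmParams = GkmParams(),
    normalize: bool | None = None,
) -> np.ndarray:
    """Kernel matrix between two sequence lists (or one list with itself,
    exploiting symmetry). ``normalize`` defaults to ``params.normalize_kernel``."""
    l, k = params.word_length, params.informative_positions
    if normalize is None:
        normalize = params.normalize_kernel
    table = _comb_table(l, k)
    wins_a = [_windows(s, l) for s in seqs_a]
    symmetric = seqs_b is None
    wins_b = wins_a if symmetric else [_windows(s, l) for s in seqs_b]
    K = np.zeros((len(wins_a), len(wins_b)))
    for i, wa in enumerate(wins_a):
        j0 = i if symmetric else 0
        for j in range(j0, len(wins_b)):
            wb = wins_b[j]
            if wa.size and wb.size:
                ham = hamming_codes(wa[:, None], wb[None, :], l)
                K[i, j] = table[l - ham].sum()
            if symmetric:
                K[j, i] = K[i, j]
    if normalize:
        diag_a = np.array([self_kernel(s, params) for s in seqs_a])
        diag_b = diag_a if symmetric else np.array([self_kernel(s, params) for s in seqs_b])
        denom = np.sqrt(np.outer(diag_a, diag_b))
        denom[denom == 0] = 1.0
        K = K / denom
    return K


def self_kernel(seq: str, params: GkmParams) -> float:
    l, k = params.word_length, params.informative_positions
    w = _windows(seq, l)
    if w.size == 0:
        return 0.0
    ham = hamming_codes(w[:, None], w[None, :], l)
    return float(_comb_table(l, k)[l - ham].sum())


class KmerWeightTable:
    """Total mapping from every l-mer to its SVM decision weight.

    Stored densely as a length-4^l vector indexed by packed code. When
    ``collapse_revcomp`` is set, a word and its reverse complement carry the
    same weight (the vector is symmetrized on construction).
    """

    def __init__(self, word_length: int, weights: np.ndarray, collapse_revcomp: bool = False):
        if not (1 <= word_length <= ENUMERATION_MAX_L):
            raise ValueError(f"word_length must be in [1, {ENUMERATION_MAX_L}]")
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (4**word_length,):
            raise ValueError(
                f"weights must have 4^{word_length} = {4**word_length} entries; "
                f"got {weights.shape}"
            )
        if not np.isfinite(weights).all():
            raise ValueError("weight table contains non-finite values")
        self.word_length = word_length
        self.collapse_revcomp = collapse_revcomp
        if collapse_revcomp:
            rc = revcomp_codes(all_codes(word_length), word_length)
            weights = (weights + weights[rc]) / 2.0
        self.weights = weights

    def weight(self, word: str) -> float:
        """Weight of a single l-mer (case-insensitive)."""
        if len(word) != self.word_length:
            raise ValueError(
                f"word length {len(word)} != table word length {self.word_length}"
            )
        return float(self.weights[kmer_to_code(word.upper())])

    def top_codes(self, n: int) -> np.ndarray:
        """Codes of the n highest-weight words (ties: lexicographic)."""
        codes = all_codes(self.word_length)
        return codes[np.lexsort((codes, -self.weights))[:n]]

    def top_kmers(self, n: int) -> list[tuple[str, float]]:
        return [
            (code_to_kmer(int(c), self.word_length), float(self.weights[c]))
            for c in self.top_codes(n)
        ]

    def rank_of(self, word: str) -> int:
        """0-based rank of a word under (weight desc, lexicographic) ordering."""
        code = kmer_to_code(word.upper())
        w = self.weights[code]
        higher = int((self.weights > w).sum())
        ties_before = int(((self.weights == w) & (all_codes(self.word_length) < code)).sum())
        return higher + ties_before

    def to_frame(self) -> pd.DataFrame:
        l = self.word_length
        return pd.DataFrame(
            {
                "kmer": [code_to_kmer(int(c), l) for c in all_codes(l)],
                "weight": self.weights,
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KmerWeightTable)
            and self.word_length == other.word_length
            and self.collapse_revcomp == other.collapse_revcomp
            and np.array_equal(self.weights, other.weights)
        )


def sequence_svm_score(table: KmerWeightTable, seq: str, summarize: str = "sum") -> float:
    """Reduce the weights of every l-window of ``seq``.

    ``sum`` is the internal reduction the deltaSVM identity relies on;
    ``average`` and ``maximum`` are the per-sequence summaries used when
    scoring whole regions. Windows with non-ACGT characters are skipped.
    """
    l = table.word_length
    if len(seq) < l:
        raise ValueError(f"sequence length {len(seq)} < word length {l}")
    codes, valid = window_codes(seq, l)
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError("sequence has no scorable (ACGT-only) window")
    vals = table.weights[codes]
    if summarize == "sum":
        return float(vals.sum())
    if summarize == "average":
        return float(vals.mean())
    if summarize == "maximum":
        return float(vals.max())
    raise ValueError(f"unknown summarizer {summarize!r}")


def topk_weight_overlap(table_a: KmerWeightTable, table_b: KmerWeightTable, k: int) -> float:
    """Percentage overlap of the top-k word sets of two tables (100 * |A∩B| / k)."""
    if table_a.word_length != table_b.word_length:
        raise ValueError("tables have different word lengths")
    if k > 4**table_a.word_length:
        raise ValueError(f"k={k} exceeds the number of words")
    a = set(table_a.top_codes(k).tolist())
    b = set(table_b.top_codes(k).tolist())
    return 100.0 * len(a & b) / k


def write_weight_table(table: KmerWeightTable, path) -> None:
    """TSV with a metadata header line; collapsed tables store canonical words
    only (code <= revcomp code), halving the file."""
    l = table.word_length
    codes = all_codes(l)
    if table.collapse_revcomp:
        codes = codes[codes <= revcomp_codes(codes, l)]
    with open(path, "w") as fh:
        fh.write(
            f"#word_length={l};collapse_revcomp={str(table.collapse_revcomp).lower()}\n"
        )
        fh.write("kmer\tweight\n")
        for c in codes:
            fh.write(f"{code_to_kmer(int(c), l)}\t{table.weights[c]:.17g}\n")


def read_weight_table(path, default_weight: float | None = None) -> KmerWeightTable:
    """Read a weight-table TSV written by :func:`write_weight_table` (or any
    kmer<TAB>weight file). Incomplete tables are rejected unless
    ``default_weight`` fills the missing words."""
    collapse = False
    word_length = None
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for field in line[1:].split(";"):
                    key, _, val = field.partition("=")
                    if key.strip() == "word_length":
                        word_length = int(val)
                    elif key.strip() == "collapse_revcomp":
                        collapse = val.strip().lower() == "true"
                continue
            kmer, _, weight = line.partition("\t")
            if kmer == "kmer":
                continue
            rows.append((kmer.upper(), float(weight)))
    if not rows:
        raise ValueError(f"no k-mer rows in {path}")
    lengths = {len(k) for k, _ in rows}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent k-mer lengths in {path}: {sorted(lengths)}")
    l = lengths.pop()
    if word_length is not None and word_length != l:
        raise ValueError(f"header says word_length={word_length} but rows are {l}-mers")
    seen: dict[int, float] = {}
    for kmer, weight in rows:
        code = kmer_to_code(kmer)
        if code in seen:
            raise ValueError(f"duplicate k-mer row {kmer!r} in {path}")
        seen[code] = weight
    weights = np.full(4**l, np.nan)
    for code, weight in seen.items():
        weights[code] = weight
    if collapse:
        rc = revcomp_codes(all_codes(l), l)
        missing_fwd = np.isnan(weights)
        weights[missing_fwd] = weights[rc[missing_fwd]]
    n_missing = int(np.isnan(weights).sum())
    if n_missing:
        if default_weight is None:
            raise ValueError(
                f"weight table {path} is incomplete: {n_missing} of {4**l} "
                f"{l}-mers missing (pass default_weight to fill)"
            )
        weights[np.isnan(weights)] = default_weight
    return KmerWeightTable(l, weights, collapse_revcomp=collapse)
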