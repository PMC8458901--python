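"""Gapped k-mer SVM model of in vivo TF binding, statsmodels-style.

:class:`GkmSvm` is constructed from data (positive = ChIP-seq-peak-like
sequences, negative = matched background sequences) and ``fit()`` returns a
:class:`GkmSvmResults` carrying the support sequences, dual coefficients,
bias and diagnostics. The exhaustive per-k-mer weight table — the quantity
everything downstream (deltaSVM, calibration, the survey) consumes — hangs
off the results object as :meth:`GkmSvmResults.weight_table`.

The optimisation itself is delegated to a generic dual solver on the
precomputed gapped k-mer kernel matrix; training is deterministic given a
fixed input order.
"""

from __future__ import annotations

import json
import warnings
from math import comb, sqrt

import numpy as np

from . import nulls as _nulls
from .alphabet import all_codes, hamming_codes, revcomp_codes
from .gkm import (
    GkmParams,
    KmerWeightTable,
    _comb_table,
    _windows,
    gkm_kernel_matrix,
    self_kernel,
)
from .io import fetch

__all__ = ["GkmSvm", "GkmSvmResults", "train_gkm_svm", "score_all_kmers"]

_PSD_TOL = 1e-8
_PSD_CHECK_MAX_N = 2000


class GkmSvm:
    """Soft-margin SVM on the gapped k-mer kernel, separating bound from
    unbound sequences.

    Parameters
    ----------
    positives, negatives : list of str
        Training sequences; every sequence must contain at least one
        ACGT-only window of length ``params.word_length``.
    params : GkmParams
    """

    def __init__(self, positives, negatives, params: GkmParams | None = None):
        self.params = params or GkmParams()
        positives, negatives = list(positives), list(negatives)
        if not positives or not negatives:
            raise ValueError("both positive and negative training sets must be non-empty")
        l = self.params.word_length
        for label, seqs in (("positive", positives), ("negative", negatives)):
            for i, s in enumerate(seqs):
                if _windows(s, l).size == 0:
                    raise ValueError(
                        f"{label} sequence {i} has no ACGT window of length {l}"
                    )
        self.sequences = positives + negatives
        self.labels = np.concatenate(
            [np.ones(len(positives)), -np.ones(len(negatives))]
        )
        self._kernel: np.ndarray | None = None

    @classmethod
    def from_intervals(
        cls,
        genome,
        peaks,
        params: GkmParams | None = None,
        null_intervals=None,
        tolerances=None,
        seed: int | None = None,
    ) -> "GkmSvm":
        """Build from peak intervals on a genome; negatives default to
        GC/repeat/length-matched non-peak intervals sampled per positive
        (``seed`` required in that case)."""
        positives = [fetch(genome, c, s, e) for c, s, e in peaks]
        if null_intervals is None:
            if seed is None:
                raise ValueError("seed is required to auto-sample matched nulls")
            null_intervals, negatives = _nulls.sample_matched_nulls(
                genome, peaks, tol=tolerances, seed=seed
            )
        else:
            negatives = [fetch(genome, c, s, e) for c, s, e in null_intervals]
        return cls(positives, negatives, params)

    def kernel_matrix(self) -> np.ndarray:
        """The (normalized, per params) training kernel matrix, cached."""
        if self._kernel is None:
            K = gkm_kernel_matrix(self.sequences, params=self.params)
            if K.shape[0] <= _PSD_CHECK_MAX_N:
                min_eig = float(np.linalg.eigvalsh((K + K.T) / 2).min())
                if min_eig < -_PSD_TOL:
                    warnings.warn(
                        f"gkm kernel matrix not PSD (min eigenvalue {min_eig:.3g}); "
                        "adding diagonal jitter",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    K = K + (-min_eig + _PSD_TOL) * np.eye(K.shape[0])
            self._kernel = K
        return self._kernel

    def fit(self) -> "GkmSvmResults":
        from sklearn.svm import SVC

        if len(set(self.labels)) < 2:
            raise ValueError("degenerate single-class training input")
        svc = SVC(C=self.params.svm_cost, kernel="precomputed")
        K = self.kernel_matrix()
        svc.fit(K, self.labels)
        support = svc.support_
        dual = svc.dual_coef_.ravel()  # signed alpha_i * y_i
        train_acc = float((svc.predict(K) == self.labels).mean())
        return GkmSvmResults(
            params=self.params,
            support_sequences=[self.sequences[i] for i in support],
            dual_coef=dual,
            intercept=float(svc.intercept_[0]),
            n_positive=int((self.labels > 0).sum()),
            n_negative=int((self.labels < 0).sum()),
            train_accuracy=train_acc,
        )


class GkmSvmResults:
    """Fitted gkm-SVM: support sequences with signed dual coefficients,
    bias, and derived quantities (decision scores, the k-mer weight table)."""

    def __init__(
        self,
        params: GkmParams,
        support_sequences: list[str],
        dual_coef: np.ndarray,
        intercept: float,
        n_positive: int,
        n_negative: int,
        train_accuracy: float | None = None,
    ):
        dual_coef = np.asarray(dual_coef, dtype=float)
        if len(support_sequences) != dual_coef.size:
            raise ValueError("one dual coefficient per support sequence required")
        if (dual_coef == 0).any():
            raise ValueError("support coefficients must be nonzero")
        if not ((dual_coef > 0).any() and (dual_coef < 0).any()):
            raise ValueError("both classes must contribute support sequences")
        self.params = params
        self.support_sequences = list(support_sequences)
        self.dual_coef = dual_coef
        self.intercept = intercept
        self.n_positive = n_positive
        self.n_negative = n_negative
        self.train_accuracy = train_accuracy
        self._table: KmerWeightTable | None = None

    # -- prediction ---------------------------------------------------------

    def decision_function(self, seqs) -> np.ndarray:
        """SVM decision values f(x) = sum_i coef_i K'(s_i, x) + b."""
        K = gkm_kernel_matrix(list(seqs), self.support_sequences, params=self.params)
        return K @ self.dual_coef + self.intercept

    def predict(self, seqs) -> np.ndarray:
        return np.where(self.decision_function(seqs) >= 0, 1, -1)

    # -- the weight table ---------------------------------------------------

    def weight_table(self, chunk_size: int = 1 << 16) -> KmerWeightTable:
        """Exhaustive SVM weights of all 4^l l-mers.

        weight(w) = sum_i coef_i * K(s_i, w) / norm, with norms matching the
        kernel normalization (sqrt(K(s_i, s_i)) per support sequence and
        sqrt(C(l, k)) per single word); bias is excluded since it cancels in
        deltaSVM differences. With ``collapse_revcomp`` each word and its
        reverse complement are averaged into a shared weight. Cached.
        """
        if self._table is not None:
            return self._table
        p = self.params
        l, k = p.word_length, p.informative_positions
        table = _comb_table(l, k)
        codes = all_codes(l)
        weights = np.zeros(4**l)
        normalize = p.normalize_kernel
        word_norm = sqrt(comb(l, k)) if normalize else 1.0
        for seq, coef in zip(self.support_sequences, self.dual_coef):
            wins = _windows(seq, l)
            scale = coef / (sqrt(self_kernel(seq, p)) if normalize else 1.0)
            for lo in range(0, codes.size, chunk_size):
                chunk = codes[lo : lo + chunk_size]
                ham = hamming_codes(wins[:, None], chunk[None, :], l)
                weights[lo : lo + chunk_size] += scale * table[l - ham].sum(axis=0)
        weights /= word_norm
        self._table = KmerWeightTable(l, weights, collapse_revcomp=p.collapse_revcomp)
        return self._table

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gapped k-mer SVM results",
            "=" * 40,
            f"{'word length (l)':<28}{p.word_length}",
            f"{'informative positions (k)':<28}{p.informative_positions}",
            f"{'SVM cost (C)':<28}{p.svm_cost}",
            f"{'kernel normalization':<28}{p.normalize_kernel}",
            f"{'revcomp collapsed weights':<28}{p.collapse_revcomp}",
            f"{'n positive / negative':<28}{self.n_positive} / {self.n_negative}",
            f"{'n support sequences':<28}{len(self.support_sequences)}",
            f"{'bias (intercept)':<28}{self.intercept:.6g}",
        ]
        if self.train_accuracy is not None:
            lines.append(f"{'training accuracy':<28}{self.train_accuracy:.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GkmSvmResults l={self.params.word_length} "
            f"k={self.params.informative_positions} "
            f"n_support={len(self.support_sequences)}>"
        )

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "params": {
                "word_length": self.params.word_length,
                "informative_positions": self.params.informative_positions,
                "svm_cost": self.params.svm_cost,
                "collapse_revcomp": self.params.collapse_revcomp,
                "normalize_kernel": self.params.normalize_kernel,
            },
            "support_sequences": self.support_sequences,
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "train_accuracy": self.train_accuracy,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GkmSvmResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=GkmParams(**payload["params"]),
            support_sequences=payload["support_sequences"],
            dual_coef=np.array(payload["dual_coef"]),
            intercept=payload["intercept"],
            n_positive=payload["n_positive"],
            n_negative=payload["n_negative"],
            train_accuracy=payload.get("train_accuracy"),
        )

    # -- plotting -----------------------------------------------------------

    def plot_weight_distribution(self, ax=None, bins: int = 80):
        """Histogram of all k-mer weights (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.weight_table().weights, bins=bins)
        ax.set_xlabel(f"{self.params.word_length}-mer SVM weight")
        ax.set_ylabel("count")
        return ax


def train_gkm_svm(positives, negatives, params: GkmParams | None = None) -> GkmSvmResults:
    """Functional shorthand for ``GkmSvm(positives, negatives, params).fit()``."""
    return GkmSvm(positives, negatives, params).fit()


def score_all_kmers(results: GkmSvmResults) -> KmerWeightTable:
    """Exhaustive weight table of a fitted model; see
    :meth:`GkmSvmResults.weight_table`."""
    return results.weight_table()
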