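# Methods

## Scope and models

The package estimates how much a bi-allelic SNV changes transcription-factor
(TF) binding, contrasting two annotations of the same variant:

1. **delta-PWM** — the difference in position-weight-matrix match
   probability between the wild-type and variant motif sequence at a
   PWM-called site;
2. **deltaSVM** — the change in a gapped k-mer SVM's sequence score, where
   the SVM is trained to separate bound (ChIP-seq-peak-like) from unbound
   sequences.

A variant inside a PWM-called putative site whose deltaSVM is *not*
significant against an empirical null is *discordant*: the classical
annotation flags it, the in-vivo-trained model does not.

### PWM

The PWM is a product-multinomial (order-zero inhomogeneous Markov) model:
columns hold per-position probabilities over ACGT; a candidate L-mer's match
probability is the product of per-position probabilities; the classical
score is its negative natural log. Internally all ranking is done on the
probability scale with "top" meaning highest probability — the negative-log
score is kept as a reporting convenience, which resolves the ambiguity of
"highest score" between the two conventions without changing any ranking.
Relative entropy, `sum_i p[i, a_i] * log(p[i, a_i] / 0.25)`, is reported
with the positive sign convention (higher = better fit); a `negate` flag
restores the opposite sign for compatibility with sources that print the
formula with a leading minus.

Counts/frequency matrices are converted to probabilities with an additive
per-cell pseudocount (default 0.25) to avoid infinite scores; matrices whose
rows already sum to one pass through unchanged (pseudocount 0). Scanning
evaluates both strands by default, skips windows containing non-ACGT
characters, retains overlapping calls, and uses 0-based half-open
coordinates throughout (VCF positions converted at the I/O boundary).
Words shorter than the motif are scored by the best of the `L - w + 1`
contiguous alignments of the word to the motif columns. Top-word
enumeration is exhaustive over `4^w` words with a deterministic tie-break
(probability descending, then lexicographic).

The scan threshold is a required user parameter. The pipeline helper
anchors it at `1e-3 x` the consensus match probability so it transfers
across simulated motifs of different strength; any absolute threshold can be
passed instead.

### Gapped k-mer SVM

A sequence is the multiset of gapped words from every l-window and every
choice of k of the l positions. The kernel is the inner product of these
count vectors; for single l-mers with m mismatches it is `C(l - m, k)`, so
sequence kernels reduce to summing `C(l - hamming, k)` over window pairs,
computed on bit-packed window codes (XOR + popcount) without materializing
features. Defaults: `l = 10, k = 6` (the gkm-SVM family's convention; k is
not dictated by the method itself and both are configurable), cost `C = 1`,
kernel normalization `K'(a,b) = K(a,b)/sqrt(K(a,a)K(b,b))` (standard for
string kernels on sequences of unequal length; a raw-kernel flag exists).
Training uses a generic dual solver (scikit-learn's SVC) on the precomputed
kernel; with fixed input order the fit is deterministic. Kernel matrices are
PSD by construction; a defensive eigenvalue check adds diagonal jitter with
a warning if numerical error ever violates that.

The exhaustive weight table assigns every l-mer
`w(x) = sum_i coef_i K(s_i, x) / norm`, with per-support norm
`sqrt(K(s_i, s_i))` and per-word norm `sqrt(C(l, k))`; the bias is excluded
because it cancels in deltaSVM differences. With reverse-complement
collapsing (default on — ChIP-seq binding signal is strand-symmetric) each
word and its reverse complement are averaged into one shared weight, which
makes deltaSVM strand-invariant. Note a consequence of normalization: the
identity "sum of window weights = decision value - bias" is exact for the
raw kernel (and is tested there), while under normalization the per-sequence
normalizer `sqrt(K(x,x))` differs from the per-word `sqrt(C(l,k))`, so the
sum-score is an affinely rescaled decision value rather than an exact one.
Exhaustive scoring is `O(4^l)`: l = 6 (4,096 words) runs in seconds and is
the desk-scale default; l = 10 (1,048,576 words) is supported but slow, and
l > 12 is refused.

### Matched nulls and control sites

Negative training sequences are rejection-sampled from outside the peak
set, one per positive, matching GC fraction, repeat fraction (fraction of
soft-masked lowercase bases) and length within tolerances of 0.02 each.
Null lengths are kept identical to their positive (relative length
difference 0), and matching is per-positive rather than distributional —
stricter and easier to verify. Sampling fails loudly (naming the positive)
after a configurable attempt cap (default 10,000); pipelines that simulate
GC-rich motifs pass a larger cap because a strongly shifted peak GC makes
0.02-matched windows genuinely rare.

Non-motif control sites are uniform motif-length windows whose match
probability stays below the scan threshold on both strands; they may
overlap one another (a `disjoint` flag forbids it) and by default are drawn
genome-wide, with an option to exclude peaks.

### Empirical null and significance

For every base of every control site the deltaSVM scores of the three
non-reference alleles are averaged; pooling over sites and positions gives
the null. Thresholds are the empirical `alpha/2` and `1 - alpha/2` quantiles
(default alpha 0.05, i.e. the 2.5th/97.5th percentiles) using linear
interpolation between order statistics — the common scientific-computing
default; nearest-rank is available and the method used is recorded in the
calibration JSON. Significance is strict (`delta < lower` or
`delta > upper`); boundary values are insignificant. The null is built from
three-variant per-base *averages* while each SNV is tested on its own
single-variant delta — the asymmetry is deliberate and preserved; a flag
to build a single-variant null exists for sensitivity analysis. With an
all-zero weight table the null collapses to a point and any nonzero delta is
significant; this degenerate behaviour is documented and tested rather than
special-cased.

The per-base averages are computed by packed-code arithmetic (substituting a
base shifts a window code by `(alt - ref) * 4^offset`), which makes the
10,000-site calibration a few seconds' work; the string-based `delta_svm` is
the reference implementation it is tested against.

### Survey

Association records with `p <= 1e-6` (boundary inclusive) are index SNVs,
deduplicated by (SNV, trait). Candidate functional variants are all panel
SNVs within ±5,000 bp (inclusive) of an index SNV on the same chromosome —
a positional proxy for LD. Each candidate overlapping a putative site
(half-open membership via interval trees, verified against brute force)
receives delta-PWM for the overlapping site with the highest wild-type
match probability (the conservative "strongest site" attachment; all
overlaps available in long format). Per (TF, trait), the discordance cell
reports overlapping and discordant counts and their percentage — absent,
not zero, when nothing overlaps. A variant within 5 kb of two index SNVs of
the same trait counts once per trait.

PWM-vs-SVM correlation takes the top-N words by PWM score (N = 1,000 at
word length 10 full scale) and computes Pearson correlation between raw
match probability and raw weight by default; log-probability and Spearman
variants are exposed because the axis scale of such comparisons is a
genuine choice, not hidden. ROC AUC uses the rank (Mann-Whitney)
formulation with tie correction, PRC AUC the step interpolation
(average precision); both sequence scorers reduce per-window values by
average or maximum.

## The simulator: what it emulates, and what it does not

`motifimpact.simulate` generates: an i.i.d. genome at a target GC (0.45,
regulatory-region-like) with geometric soft-masked repeat tracts (0.2
tracts/kb, mean 150 bp); a 12-bp motif with 8 conserved positions (dominant
base probability drawn from [0.92, 0.98]; degenerate columns Dirichlet(8),
near-uniform); 60 non-overlapping 150-bp peaks avoiding masked tracts, each
with 3 motif instances sampled from the PWM (not the consensus, so training
sees realistic degeneracy); 120 motif SNVs split evenly between conserved
and degenerate instance positions plus 120 background SNVs; and an
association table with 6 background index SNVs at `p < 1e-6` across 3
traits. Peak length, planting rate and GC were fixed once such that the
planted signal is strong in the intended sense — a scan at the default
threshold recovers over 90% of planted instances and peak/background
separation is comfortable — while keeping GC-matched null sampling
feasible; they were not revisited afterwards. Every stage draws from an
independent substream of the mandatory seed, so regenerated studies are
byte-identical.

What the simulator does **not** emulate: chromatin accessibility,
mappability structure, GC heterogeneity beyond i.i.d. sampling, realistic
LD (the 5 kb window is purely positional), cooperative or
dependent-position binding, and cell-type-specific signal. Passing tests
therefore demonstrate internal correctness and recoverability of planted
signal under clean conditions — not performance on real ChIP-seq, where
data quality, confounded covariates and motif misspecification all bite.

## Problem sizes and numerical choices

Tests run at word length 6 (4,096 words) with 300–1,000 control sites; the
acceptance script uses the full 10,000 control sites. Both complete in
seconds to minutes on a single CPU; these sizes are the package's chosen
desk-scale conditions, with the full-scale values (l = 10, 10,000 sites)
one configuration flag away. Probability products are computed directly in
double precision (motif lengths here keep them far from underflow; the
enumeration caps at 4^12). Ties in every ranked list break
lexicographically so all outputs are deterministic. Degenerate inputs —
empty classes, sequences without a scorable window, sites without flanks,
zero-variance correlations (NaN sentinel), sub-40-value nulls (warning) —
fail or warn explicitly rather than silently.

## Known limitations

- Exhaustive `4^l` weight scoring is the method's honest cost; genome-scale
  l = 10 tables take minutes-to-hours here since no truncated/approximate
  kernel is implemented.
- The SVM is trained on whole peak sequences; no summit-centering or
  fragment-size modelling is attempted.
- delta-PWM is only defined inside PWM-called sites, so the discordance
  table inherits the scan threshold's arbitrariness; the threshold is
  surfaced as an explicit parameter everywhere.
- Hyperparameters (k, cost, normalization) follow the gkm-SVM family's
  conventions; numerical agreement with any specific external gkm tool is
  not claimed.
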