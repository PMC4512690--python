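# Methods

## Problem and pipeline

The package classifies 12 scripted physical activities from tri-axial
acceleration recorded at the wrist, chest and ankle at 100 Hz.  The
pipeline is: (1) read labeled recordings; (2) cut each sensor stream into
5 s windows advanced by 1 s, never crossing an activity boundary; (3)
compute a per-axis bank of time-domain statistics plus inter-axis
correlations; (4) optionally reduce the feature set by correlation-based
feature selection (CFS) searched with a scatter search; (5) train one of
three classifiers on a stratified 70/30 instance split and report
per-class precision/recall/F with support-weighted averages.

## Windowing

Windows are defined in sample counts (`N = round(f_s · w_t)`,
step `= round(f_s · slide)`), not wall-clock time, so timestamp jitter
cannot change instance counts.  With the defaults (w_t = 5 s, slide = 1 s,
100 Hz) successive windows overlap by 4 s; a single-activity bout of `L`
samples yields `⌊(L − 500)/100⌋ + 1` windows.  The "slide = 1 s" reading
of the overlap convention is the one consistent with the instance counts
the 39/117-feature protocol implies; it is configurable.  Bouts labeled
with the transient/break code are excluded from windowing by default
(`include_transient=True` restores them).

## The feature bank

Thirteen per-axis statistics are implemented (MAV, WMAV₁, WMAV₂, harmonic
mean, variance, RMS, skewness, kurtosis, cumulative length, zero
crossings, Willison amplitude, slope-sign changes, signal energy).  The
default bank drops the signal energy (SSI): SSI = N·RMS² is a
deterministic monotone function of RMS, so it adds no information, and a
12-statistic bank is what yields the canonical widths of 39 per sensor
and 117 fused.  `include_ssi=True` restores it (42/126).  Column order is
frozen and axis-major (`placement.x.*`, `placement.y.*`, `placement.z.*`,
then `placement.corr.xy|xz|yz`) so indices are reproducible across runs.

Parameter defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `window_seconds` | 5 s | window length w_t |
| `slide_seconds` | 1 s | window advance |
| `willison_threshold` | 0.5 m/s² | ε for the Willison amplitude; no canonical value exists, so it is always explicit in config and logged |
| `degenerate_tolerance` | 1e-12 | σ below which skewness/kurtosis/correlations return the guard value 0 |
| `missing_max_frac` | 0.1 | windows with a larger missing fraction are dropped |
| `demean` | off | features are computed on raw acceleration so postural gravity offsets stay discriminative |

Numerical choices worth knowing:

* **Guards.** Harmonic mean returns 0 when any sample is exactly zero (the
  quantity is undefined there, and classifiers need finite inputs;
  measure-zero for real sensors).  Skewness, kurtosis and correlations
  return 0 for (near-)constant windows.  `extract_features` additionally
  maps any residual non-finite value to 0, so emitted matrices are always
  finite.
* **Zero crossings / slope-sign changes** use strict inequalities: pairs
  touching an exact zero and plateaus do not count.
* **Willison amplitude** counts strictly-greater-than-ε differences.
* **Harmonic-mean summation.** The reciprocal sum of signed samples can
  cancel almost completely; the scalar path uses exact (`fsum`)
  summation and the vectorized kernel extended precision, so both agree
  with a direct-formula oracle to 1e-12 relative.
* Variance, skewness and kurtosis use population (divide-by-N)
  normalization throughout.

## Missing data

Wireless dropouts appear as NaN samples.  Policy (the recording format is
silent on this, so it is the package's own): linear interpolation fills
gaps of at most `interpolation.max_gap_s` (default 0.1 s) strictly inside
an activity bout; windows whose missing fraction exceeds 10% are dropped;
smaller residual gaps inside kept windows are linearly interpolated with
edge hold.  Counting windows is therefore label-driven unless dropouts are
substantial.

## Feature selection: CFS + SS-RGS

A subset S of k features scores
`merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)`.  Feature–class relevance r_cf
for a nominal 12-level label is the class-prior-weighted mean of absolute
point-biserial correlations against each one-vs-rest indicator; integer
coding of the label was rejected as order-dependent.  Feature–feature
redundancy r̄_ff is the mean pairwise |Pearson r|, cached and filled
lazily per column.

The search is a sequential scatter search with reduced greedy combination:

1. **Diversification** (default pool 30): sizes stratified over
   1..width/2, membership drawn least-used-feature-first with random
   tie-breaks, so every feature is represented when the pool is at least
   as large as the width.
2. **Improvement**: best-improvement hill climbing over single additions
   and removals; a fixed point of the merit, hence idempotent.
3. **Reference set** (default 10): half best-merit, half maximally diverse
   by minimum symmetric-difference distance to current members.
4. **Combination**: for every pair, start from the intersection and
   greedily add the merit-maximizing feature from the union only.
5. **Update**: static re-rank of reference set ∪ improved children;
   the loop stops when an iteration inserts no new member (the stopping
   threshold is qualitative in the source literature; stagnation is the
   deterministic choice) or after `max_iterations` (50).

All randomness flows from one seed; the search is reproducible
bit-for-bit.  On matrices of ≤ 12 features the search attains the
brute-force CFS optimum in ≥ 90% of seeds (tested); no particular
cardinality of the selected subset is promised on real data, since that
depends on the search seed and data split.

## Classifiers

All three share min–max scaling fitted on training data only (constant
features scale to 0; test values may leave [0, 1]).  Training rows are
put in a canonical label-major order first, making every model invariant
to the order instances arrive in.

* **KNN** (K = 3): Euclidean distance on scaled features; majority vote,
  ties broken by smallest mean neighbor distance, then label order.
* **Rotation forest** (M = 10 trees, subsets of 3 features, 75%
  class-bootstrap): per tree, features are randomly partitioned; per
  subset a random nonempty set of classes is drawn, a bootstrap of 75% of
  their instances taken, and the principal axes of that sample form one
  orthonormal block of a block-diagonal rotation; an unpruned Gini CART
  (minimum leaf 2) is trained on the fully rotated data.  Prediction
  averages the trees' class distributions.  Blocks satisfy BᵀB = I to
  1e-8 (tested).  M and the base-tree settings follow common ensemble
  practice; they are configurable.
* **MLP**: one hidden layer of `(features + classes)/2` logistic units,
  plain-momentum SGD (rate 0.3, momentum 0.2, 500 epochs) — the classic
  toolkit defaults for this architecture — via scikit-learn's
  `MLPClassifier` with regularization disabled.

## Evaluation

`split` partitions instances exactly into `round(0.7·n)` training and the
remainder, stratified by class (with a warned fallback to a plain split if
a class has fewer than 2 instances).  Metrics come from the confusion
matrix with rows = true classes: precision per predicted column, recall
per true row, F their harmonic mean; zero-denominator classes report 0 and
are flagged.  Averages are support-weighted (the headline convention;
weighted recall ≡ accuracy) with unweighted macro averages alongside.
Display rounding is 3 decimals, half-up.

Five reference confusion matrices from a published wrist/chest/ankle
activity-recognition benchmark ship as packaged CSVs and pin the metric
arithmetic in regression tests.  Recomputing per-class metrics from the
wrist, chest, ankle and reduced-feature-set matrices reproduces the
benchmark's published metric tables to ±0.001 after rounding; the
combined-sensor matrix is internally inconsistent with its published
table (weighted averages 0.975 vs 0.982–0.983), so its matrix-derived
values are pinned instead and the discrepancy documented here rather than
forced into agreement.

## Synthetic benchmark

The generator models each activity per sensor as a posture DC offset plus
a few sinusoids (0.5–3.5 Hz fundamentals with harmonics, all far below
the 50 Hz Nyquist limit) plus Gaussian noise; rope jumping adds 0.8-deep
amplitude modulation at 0.25 Hz to mimic bursts.  Lying and standing
differ only in gravity direction; ascending and descending stairs are
parameterized closest together so they remain the hardest pair.  Per-bout
random phases and ~5% amplitude jitter make different seeds act like
different subjects.  The default benchmark is 5 subjects × 60 s per
activity (3,360 fused instances), a size chosen to exercise the full
pipeline in seconds while leaving headroom above the 95% recovery bar.

What passing the synthetic tests shows — and does not.  The generator
exercises every feature pathway (DC, amplitude, cadence, correlation
structure) and the full mechanical chain from raw samples to reports, so
recovery failures would localize real defects.  It does not emulate
sensor saturation, orientation drift, between-subject biomechanics,
autocorrelated noise or realistic dropout bursts, so near-perfect
synthetic accuracy says nothing quantitative about accuracy on real
recordings; the real-data checks live in the two tests that require the
PAMAP2 protocol files on disk.

## Known limitations

* Frequency-domain and wavelet features, gyroscope/magnetometer/heart-rate
  channels, and per-subject (leave-one-subject-out) evaluation protocols
  are out of scope; the split is a random instance-level partition, which
  is optimistic relative to subject-wise generalization.
* Which of the 13 listed statistics to drop to reach the canonical
  12-per-axis bank is an assumption (SSI, as the only deterministic
  duplicate); the flag restores it.
* The CFS relevance construction for nominal labels is one of several
  defensible choices; alternatives (e.g. symmetric-uncertainty CFS) are
  deliberately not implemented.
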