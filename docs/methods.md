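# Methods

## Sequence descriptor: CKSAAP

For a validated sequence `s` of length `L` over the 20 standard
amino-acid letters and a maximum gap `k`, the composition of k-spaced
amino acid pairs counts, for each gap `j = 0..k`, every ordered pair
`(s[i], s[i+j+1])` (overlapping occurrences all count).  Each gap
contributes a block of 400 ordered pairs; blocks are stacked to a vector
of length `400·(k+1)`.

By default each gap-`j` block is divided by the number of available
positions `L − j − 1`, so entries are pair frequencies in `[0, 1]` and a
block sums to 1 whenever `L > j + 1`.  This normalisation matches the
sigmoid-output decoder, which can only reproduce values in `(0, 1)`; a
raw-count mode is kept behind `CksaapConfig(normalize=False)`.  The
alternative (raw counts) changes the input scale but not the pair
ordering contract.

Ordering is part of the on-disk format and is fixed: alphabet
`ACDEFGHIKLMNPQRSTVWY`, pairs `AA, AC, …, YY` within a block
(`index = 20·first + second`), blocks `j = 0..k`, CSV columns named
`j{gap}_{pair}`.  A sequence too short for some gap (`L < j + 2`) yields
an all-zero block and a warning rather than an error, so short peptides
remain encodable.

## Model and training

The network has three modules:

* encoder `400·(k+1) → N·10 → N·5 → N·2 → LV`, latent activation sigmoid
  (latent codes live in `[0,1]`, the same range as the features);
* decoder, the exact mirror of the encoder, sigmoid output;
* classifier `LV → 10 → 10 → 2`, softmax output.

Hidden layers use ReLU with batch normalisation and 30% dropout in the
block order dense → batch-norm → activation → dropout (the order is a
convention choice; only the presence of the layers is fixed by the
architecture).  The classifier hidden width is fixed at 10 regardless of
`N`.  The loss is the convex combination
`L = λ·MSE(x, x̂) + (1−λ)·CE(y, p)` with `λ = 0.99`; the two-class
"binary cross-entropy" is implemented as categorical cross-entropy on
one-hot targets, the identical quantity for two classes.  MSE is the
mean over all feature dimensions and samples.

Optimisation is RMSprop at its conventional default learning rate 0.001
(ρ = 0.9, ε = 1e−7), minibatch size 32, up to 1000 epochs with early
stopping at patience 100 monitoring the *validation* combined loss; the
best-epoch parameters are restored.  The validation set is a stratified
10% of the training set carved out before training — monitoring an
internal split rather than the test set avoids leakage.  All randomness
(initialisation, the validation split, shuffling, dropout masks) flows
from one `numpy.random.Generator` seeded by `ModelConfig.seed`, so runs
are bit-reproducible; repeated-trial runs use `base_seed + t`.

The neural-network core is a compact NumPy implementation (dense,
batch-norm with running statistics, inverted dropout, fused
softmax/cross-entropy head, RMSprop) — small enough to audit, and
sufficient for the model sizes involved (≈10⁵ parameters).  Minibatches
of fewer than two samples are skipped because batch statistics are
undefined there.  Batch-norm numerics follow the common framework
defaults (momentum 0.99, ε = 1e−3).

Degenerate predictions: a softmax tie (0.5/0.5) is resolved to the
negative (majority) class.  No class weighting or resampling is applied
by default.

## Metrics

Sensitivity, specificity, precision, accuracy, MCC, balanced accuracy,
Youden's index, F1, and Cohen's κ (via observed/expected agreement Po,
Pe) are computed directly from the confusion counts.  Any metric with a
zero denominator (e.g. precision with no predicted positives, MCC with a
zero marginal, F1 at precision + recall = 0) is reported as NaN
("undefined") rather than coerced to 0; aggregation over repeated trials
skips undefined values and reports how many were skipped.  Silent zeros
would bias means in small-trial ablations, which is exactly where
degenerate all-one-class predictors appear.

Reconstruction error is reported as `−10·log₁₀(MSE)` decibels; for
features in `[0, 1]` this equals PSNR with peak 1.  Identical matrices
give +∞ dB, reported as such.

ROC-AUC and PR-AUC are computed from the positive-class scores with
standard trapezoidal routines (scikit-learn).

## Separability diagnostics: GCNR

The generalized contrast-to-noise ratio of two 1-D sample sets is
`1 − Σᵢ min(h⁺ᵢ, h⁻ᵢ)` over histograms sharing `bins` equal-width bins
on the pooled min–max range, each normalised to sum 1.  A score of 1
means no overlap (perfectly separable), 0 means identical distributions.
For multivariate representations the score is taken along the first
principal component (1D-PCA-GCNR).  PCA component signs are fixed by
forcing the largest-magnitude loading positive, so scores are
reproducible across libraries and runs.

Histogram parameters: 100 bins by default.  Note the estimator has a
positive small-sample bias of order the expected L1 distance between two
empirical histograms of the same distribution: with 100 bins it is
roughly 0.3 at 500 samples and 0.15 at 2000, shrinking with samples per
bin.  Scores at different sample sizes or bin counts are therefore not
directly comparable; comparisons in this package (latent vs feature
space, joint vs conventional autoencoder) always use the same samples
and bins on both sides.  t-SNE (perplexity 30, clamped to
`(rows−1)/3`, seeded) is provided for visualisation only and never used
for scoring decisions.

## Synthetic benchmark generator

The generator emulates the shape of curated antioxidant benchmarks so
the whole pipeline is testable without external downloads:

* 253 positives / 1552 negatives (split 200/1240 train, 53/312 test by
  a seeded, class-stratified partition with exact counts); sequence
  lengths uniform on 50–600;
* each sequence draws its own residue composition from
  `Dirichlet(concentration · background)` with concentration 25 around a
  uniform background (per-residue frequency s.d. ≈ 0.04).  Real
  proteins vary substantially in composition, and this variation — not
  the class signal — dominates the leading principal components of the
  raw pair-frequency space, as observed in real benchmarks.  Setting
  `composition_concentration=None` disables it;
* positives are then enriched: for each motif `(a, b, gap j, weight w)`
  a Poisson-distributed number of anchors at per-position rate
  `effect_size · w / 100` is overwritten with `a` at `i` and `b` at
  `i+j+1`.  Overwriting (not inserting) keeps length uninformative about
  class.  At the default effect size 5 each planted pair reaches ≈5% of
  positions in positives against a ≈0.25% background frequency;
* the default motif set places pairs at gaps {0, 2, 6}, so a sweep of
  the gap parameter has a detectable optimum near k = 6 while small-k
  models still see signal; `effect_size = 0` reduces positives to the
  null exactly.

What passing on this generator does **not** show: real antioxidant
sequences carry homology structure, domain architecture and
length/composition confounds that i.i.d. residue sampling does not
reproduce, so synthetic performance says the *pipeline* recovers planted
k-spaced pair signal — not that any particular accuracy transfers to
real proteins.

## Frozen-autoencoder baselines

To isolate the value of joint training, a reconstruction-only
autoencoder (identical widths, `λ = 1`) is trained on the same data, its
latent codes frozen, and three classifiers fitted on the codes: the same
MLP head architecture, an RBF-kernel SVM (C = 1000, balanced class
weights), and Gaussian naive Bayes with equal priors.  All models are
scored on the identical test split.  On frozen codes the MLP head
sometimes collapses to the all-negative predictor (undefined MCC under
the zero-denominator policy); for ordering comparisons such a collapsed
baseline is counted as not exceeding the joint model.

## Problem sizes used in tests and the acceptance script

The package defaults keep the full training schedule (1000 epochs,
patience 100).  The test suite and the acceptance script run desk-scale
versions chosen once: the benchmark-shaped runs use `k = 2, LV = 4,
N = 5` with `max_epochs = 150, patience = 25` (the strongly planted
signal converges well within this schedule), and the small unit-test
fixtures use 80/240 sequences of length 50–150 at effect size 8.
Repeated-trial and ablation examples use 1–5 trials rather than 20; all
aggregates remain recomputable from the stored per-trial records.

## Known limitations

* The NumPy training core is single-threaded BLAS-bound; it is intended
  for the benchmark scale (10³–10⁴ sequences), not large proteome scans.
* GCNR bin-count sensitivity is the user's responsibility; the report
  carries the bin count and class sizes so scores are interpretable.
* The conventional-autoencoder comparison shares the encoder
  architecture but not a shared initialisation trajectory with the joint
  model beyond the common seed; differences at very small data sizes are
  noisy.
* Probabilities from the softmax head are not calibrated.
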