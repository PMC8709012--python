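# Methods

This note documents the models and procedures fundusnet implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## The feature extractor

The extractor is a residual CNN followed by a recurrent read-out:

* **Stem.** A 3×3 convolution with stride 2 (8 filters by default), batch
  normalisation, ReLU.
* **Residual blocks.** Six blocks by default, filter widths
  (16, 16, 32, 32, 64, 64). Each block is conv→BN→ReLU→conv→BN; the block
  input is added back before a final ReLU. When the channel count or
  stride changes, the skip path carries a 1×1 projection convolution.
  Every second block downsamples with stride 2, so a 125×125 input
  reaches an 8×8×64 map (the error message for too-small inputs reports
  the minimum feasible size for the configured schedule).
* **Sequence read-out.** The final H×W×C map is unfolded into H timesteps
  of length W·C (W-major, then channels) and read by an LSTM (100 units
  by default); the last hidden state summarises the map. The LSTM uses
  the standard forget/input/output gates on the concatenation
  [h_{t−1}, x_t], with the forget bias initialised to 1.
* **Head.** FC1 (width 350) → ReLU → dropout (rate 0.2) → FC →
  softmax. *Deep features* are the FC1 activations taken pre-ReLU: the
  sign information is preserved and the choice is configurable in
  spirit — post-ReLU features are one `relu()` call away.

Variants: `cnn` and `cnn_lstm` drop the skip connections; `cnn` and
`rcnn` replace the LSTM read-out with flattening.

Filter counts, strides and the downsampling schedule are not dictated by
the architecture's headline constants (six blocks, 100 LSTM units, 350
FC1 width, 125-pixel inputs); the defaults above were chosen so the
full-size network stays under half a million parameters while meeting
those constants.

Training uses softmax cross-entropy with SGD-with-momentum
(batch 128, learning rate 0.001, momentum 0.9, up to 150 epochs by
default). Everything — convolution via im2col, batch-norm, BPTT through
the LSTM, the optimiser — is implemented in numpy with hand-written
backward passes, validated against central finite differences in the test
suite, and is deterministic for a fixed seed and data order.

Batch normalisation follows the population (1/n) variance convention in
both the trainable layer and the scalar reference implementation; the
trainable layer keeps exponential running statistics (momentum 0.9) for
inference.

## NCA feature weighting (NCAR level 1)

Weights maximise

F(w) = (1/n) Σᵢ Pᵢ − λ Σᵣ wᵣ²,

where Pᵢ is the probability that sample i's stochastic nearest neighbour
shares its class under the soft-neighbour kernel
p_ij ∝ exp(−d_w(xᵢ,xⱼ)/σ), p_ii = 0, with the weighted L1 distance
d_w(xᵢ,xⱼ) = Σᵣ wᵣ² |x_ir − x_jr|. Squaring the weight inside the
distance keeps the effective weight non-negative and consistent with the
wᵣ² penalty; since only wᵣ² enters the model, fitted weights are reported
as magnitudes.

Choices and defaults:

* λ defaults to 1/n (the common heuristic; configurable — the objective
  is meaningless at extreme λ, where all weights collapse).
* σ = 1 after z-scoring each column (default `standardize=True`), which
  makes the kernel scale-free.
* Optimisation starts from w = 1. The default solver is gradient ascent
  with a backtracking line search (step halved on objective decrease, so
  the recorded objective trace is non-decreasing; stop at relative
  improvement below `tol` = 1e−6 or `max_iters` = 100). An L-BFGS solver
  (`solver="lbfgs"`) is available and is used by the pipeline: the true
  maximiser sets the weight of every feature whose marginal utility falls
  below λ to exactly zero, and the quasi-Newton solver resolves those
  near-zero weights where first-order ascent leaves them slowly decaying.
  This matters whenever a small threshold (0.0005) is applied to the
  fitted weights.
* Degenerate all-identical rows give zero distances and a uniform kernel
  (the softmax limit), not an error.
* The analytic gradient is
  ∂F/∂wᵣ = (2wᵣ/(nσ)) Σ_ij (Pᵢ − hit_ij) p_ij |x_ir − x_jr| − 2λwᵣ,
  checked against central finite differences at 1e−6 relative tolerance.
* The pairwise |Δ| tensor is cached when it fits in ~0.6 GB and chunked
  otherwise, so repeated objective/gradient evaluations cost one BLAS
  product each.

## ReliefF weighting (NCAR level 2)

Weights start at zero and accumulate, over m probe instances, a penalty
for each of the k nearest same-class neighbours (hits) and a
prior-weighted reward for each of the k nearest neighbours of every other
class (misses), using the range-normalised difference `diff`. With
`diff` ∈ [0,1] and the miss terms weighted by P(C)/(1−P(class(Rᵢ))), every
weight lies in [−1, 1].

Choices and defaults:

* k = 10 nearest neighbours (configurable; an alternative convention ties
  k to the number of classes minus one, but k = 10 is the operating point
  used with the thresholds below). k is clipped with a warning when a
  class is too small.
* m = "all": every instance probes once, in index order, making the
  result exactly deterministic; integer m samples probes without
  replacement under the config seed.
* Neighbour search uses Manhattan distance on range-normalised features
  (consistent with `diff`); self-matches are excluded and ties break by
  lowest instance index.
* Constant features have zero range and contribute exactly 0.
* Implementation is verified feature-for-feature against an exhaustive
  double-loop oracle on 30 random small instances.

## NCAR

`ncar_select` chains the two levels: NCA weights thresholded at 0.0005
(weights ≥ threshold survive), then ReliefF weights *recomputed on the
surviving columns* and thresholded at 0.01, with the final mask mapped
back to original column indices. Raising either threshold can only
shrink the selected set (nesting), and an emptied level 1 raises an error
advising a lower threshold.

`ratio_reduce` is a separate single-vector reduction — mean and
population-std ratios against a threshold, statistics computed once from
the input — kept for completeness; it is not part of the two-level
selector.

## Evaluation

Stratified k-fold cross-validation (k = 10 default, reduced with a
warning when a class has fewer members) with features z-scored using
training-fold statistics only. Per-fold predictions pool into one
confusion matrix; sensitivity, specificity, precision and F-score are
one-vs-rest per class, macro averages are unweighted means, and AUC is
one-vs-rest per class from decision scores, macro-averaged. Undefined
ratios (empty denominators) are NaN with a warning and excluded from
macro averages.

Classifiers: decision tree, linear discriminant analysis, Gaussian naive
Bayes (continuous features), SVM (RBF kernel default), k-nearest
neighbours (k = 1 default) — all via scikit-learn with hyperparameters
exposed.

`run_pipeline` has two modes, made explicit because they answer different
questions. **paper** mode trains the extractor and fits the selector on
the full dataset and cross-validates only the classifier; this mirrors
the original study design but leaks extraction/selection information
across folds, so its accuracies are optimistic — it is the default for
fidelity, and this caveat is the reason **honest** mode exists, nesting
extraction and selection inside each fold.

## Synthetic data

**Feature tables.** Class means for the informative columns sit on a
regular simplex (tiled cyclically when there are more informative columns
than classes minus one) rescaled so the *closest* pair of class means is
`effect_size · noise_sd` apart; all columns carry i.i.d. Gaussian noise
with `noise_sd`, and non-informative columns are pure noise. Labels are
balanced within one sample. Defaults (n = 500, p = 40, 8 informative,
8 classes, effect size 3) are the selector benchmark conditions.

**Phantom images.** Eight classes of fundus-like 125×125 (configurable,
min 32) RGB images: a dark circular field with radial shading, an offset
optic disc, and dark vessel arcs; per class, one distinguishing structure
with seeded jitter in position/size/amplitude (AMD: macular drusen
cluster; Cataract: heavy blur plus a milky veil; Diabetes: scattered
bright exudates and dark dots; Glaucoma: enlarged bright disc and cup;
Hypertension: more numerous, strongly tortuous vessels; Normal: field,
disc, vessels only; Other: one large irregular grey lesion; PM: pale
peripapillary crescent and washed-out fundus), plus Gaussian sensor
noise. One global seed feeds independent per-stream generators for
tables and images, so adding a stream never perturbs existing outputs;
images are written as lossless PNG.

These phantoms are separable texture cartoons, not anatomy. Passing
tests on them demonstrates that the machinery — training, extraction,
weighting, thresholding, cross-validation — is correct and
well-conditioned; it says nothing about clinical accuracy on real fundus
photographs, which depends on signal the phantoms do not model (camera
variation, graded pathology, class imbalance, label noise).

## Benchmark problem sizes

The test suite and the acceptance script run the pipeline at phantom
scale: 8 × 40 images at 32 px, a two-block extractor with a 16-unit LSTM
and the full 350-wide FC1, 40 training epochs. The wide FC1 over a
narrow recurrent state reproduces, at small scale, the redundancy that
makes multilevel selection worthwhile: NCAR typically keeps under 10% of
the 350 columns with no loss of cross-validated accuracy. Selector
recovery is benchmarked on 20 seeded tables at the default table
conditions above.

## Known limitations

* CPU-only numpy training: practical for phantom-scale experiments, not
  for thousands of full-resolution clinical images.
* No data augmentation or class-imbalance handling in the trainer.
* ReliefF implements the numeric `diff` only (deep features are
  continuous); nominal/missing-value variants are out of scope.
* NCA learns per-feature weights, not a projection; it is a selector
  here, not a dimensionality reducer.
* Paper-mode cross-validation overstates generalisation by design (see
  above); honest mode is the defensible estimate.
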