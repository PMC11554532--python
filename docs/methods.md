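# Methods

## Overview

The package implements a five-stage classification framework for fetal
ultrasound standard planes: (1) construction and SGDM training of two
custom residual CNNs, (2) Bayesian optimization of training
hyperparameters, (3) GAP deep-feature extraction, (4) metaheuristic
wrapper feature selection with serial fusion, and (5) shallow
neural-network classification with a full multiclass metric suite and a
paired classifier-comparison t-test. All stages run offline at desk
scale against synthetic data with known ground truth.

## Architectures

The two networks are stored as explicit layer DAGs (`ModelGraph`) and
assembled layer-by-layer from their published descriptions. Conventions
where the descriptions are silent or inconsistent:

- **Input** is 224×224×3 (the datasets are loaded as 3-channel
  grayscale); builders require spatial dims ≥ 32 — below that the
  stride-2 stack degenerates before global pooling, and the builder
  raises a configuration error naming the offending dimension.
- **Padding**: all convolutions and pools use "same"-style padding;
  stride-2 layers halve spatial dims with ceil division. This is the
  only convention under which the deep stride-2 stacks keep a positive
  spatial extent down to the GAP layer.
- **Consecutive ReLUs** collapse to one (ReLU∘ReLU = ReLU); the graphs
  record a single relu node, and an engine-level test verifies the
  collapse changes no forward output.
- **Shortcuts**: the builder inserts a 1×1 projection convolution on a
  shortcut path whenever the two inputs of an add layer would disagree
  in channel width (standard residual practice; the default builds
  never need one, since every block's trailing convolution restores the
  trunk width).
- The 3-block model carries no batch normalization; the 4-block model
  has one batchnorm per residual block. Convolutions carry biases.
- **`width_scale`** multiplies every channel width uniformly (floor 1).
  The default 1.0 reproduces the published widths, including the
  2048-wide GAP output both models share; scaled-down builds keep the
  exact topology and make CNN training tractable on a laptop CPU.

**Parameter accounting.** `infer_shapes` counts k²·c_in·depth + depth
per convolution, 2·c per batchnorm, c_in·depth + depth per fully
connected layer. The faithful enumerations total ≈174.6M (3-block) and
≈157.7M (4-block) learnable parameters: the descriptions place 3×3
convolutions at 1024→1024 and 1024→2048 channels, single layers of
9.4M and 18.9M parameters, so the published totals of 3.77M and 18.87M
(and the ResNet-18/ResNet-50 budget comparisons) cannot be reproduced
from the published layer lists under any bias or projection convention.
The package reports the honest counts; the corresponding acceptance
check is expected to fail and is left failing rather than adjusted.

## Training

The numpy engine executes the graphs in NHWC layout with im2col
convolutions and runs SGDM (classical momentum, L2 penalty on weights
only). Defaults in `TrainConfig` are the published
Bayesian-optimization-selected values: learning rate 2.74e-4,
mini-batch 128, momentum 0.699, L2 weight 1e-6. Numerical choices:

- **Initialization**: He-normal on the *effective* receptive field
  min(k,h)·min(k,w)·c_in. Once the feature map is smaller than the
  kernel, padding zeroes most taps; the nominal k² fan-in would shrink
  activations ≈3× per layer through the long 1×1 tail of these
  architectures and freeze learning. The classifier head initializes at
  zero so an untrained network predicts uniformly (initial
  cross-entropy ln k).
- **Warmup**: 3 epochs of linear learning-rate warmup guard the
  batchnorm-free 3-block stack against early ReLU die-off.
- **Early stopping** on a 10% validation slice with patience 10 (epoch
  budget 50 by default; the published account does not state one).
- Mini-batches shrink to the dataset size when the data is smaller
  than the configured batch.
- The desk-scale pipeline trains width-scaled models (scale 1/8,
  20 epochs, learning rate 1e-3, momentum 0.699) — settings chosen so
  the miniature networks optimize in seconds, not as claims about the
  full-scale regime.

Split convention: stratified, train receives ceil(n_class·fraction)
(1386 → 693/693, 1281 → 641/640 at 0.5). Evaluation convention: the
CNNs are trained once on the 50% train split; downstream classifier
metrics use stratified 10-fold cross-validation on features extracted
from the held-out half, with out-of-fold predictions pooled and scored
once.

## Bayesian optimization

Gaussian-process surrogate with a Matérn 5/2 ARD kernel plus white
noise, hyperparameters by marginal-likelihood maximization (two
restarts); observations are standardized internally. Acquisition is
closed-form expected improvement for minimization, maximized over a
2048-point random pool with L-BFGS-B refinement of the pool optimum.
Integer parameters round at evaluation time; the learning rate is
searched on a log scale over [1e-5, 0.999] so the published optimum
2.74e-4 is representable (the published range 0.01–0.999 excludes its
own reported value). Non-finite objective values are recorded as failed
evaluations with a 1e6 penalty. The search demonstrates on surrogate
objectives and tiny training runs; full CNN-training objectives are
GPU-scale and out of scope.

## GNDO

One `numpy` Generator drives the whole run; the draw order is fixed
(per individual: the strategy coin α; local move: a, b, then
componentwise λ₁, λ₂; global move: peer indices p₁,p₂,p₃, then β, γ₃,
γ₄), so a fixed seed reproduces traces bitwise. Implementation
decisions:

- The generalized standard variance carries the square root (root mean
  squared deviation), giving it distance units.
- Penalty factor η = √(−log λ₁)·cos(2πλ₂) with a π phase flip when
  a > b — zero-mean and heavy-tailed (verified by Monte-Carlo in the
  tests).
- Trials clamp componentwise to the box bounds before evaluation, which
  preserves the screening guarantee; screening keeps the incumbent on
  ties (strict improvement only), so the best-so-far trace is monotone.
- α is drawn per individual per iteration.

On the 10-D sphere at the published budget (population 20, 200
iterations) the optimizer reaches ≈3e-2–1e-1 and beats equal-budget
random search by two to three orders of magnitude.

## IGNDO feature selection

Positions live in [−4, 4]^D so logistic scores can approach 0/1 without
saturating the score map's gradient. Scores clip at ε = 1e-12 before
logs. The scalar threshold CE is the mean binary cross-entropy of the
score vector against its own 0.5-binarization; the mask keeps feature j
iff pⱼ ≥ CE, with a fallback to the 0.5 rule (and a logged warning) if
the mask would be empty.

**Wrapper fitness.** Each candidate position is scored by the hold-out
error (stratified 30% split, fixed per run) of a nearest-centroid
classifier restricted to the position's *CE-thresholded* columns — the
same mask rule the selector finally emits, so the search optimizes
exactly the quantity that defines the result — plus a small continuous
term 0.25·mean(p). The continuous term matters: a pure 0-1 error is
piecewise constant in 100-D score space and leaves the greedy screening
tie-locked (sub-threshold score components feel no pressure at all),
whereas the score-mass term breaks every tie in favor of sparser,
more polarized score vectors. Error remains dominant: dropping a useful
feature costs percentage points of error while saving at most
0.25/D in mass.

**Known behavior**: because CE lands below 0.5 (≈0.3 for mixed-
confidence score vectors), features whose scores hover between CE and
0.5 — "off" during the search — re-enter the final mask, and the
population-contraction dynamics of GNDO pull unfitted dimensions toward
score 0.5. Selected widths on the 300×100 planted benchmark are
therefore ≈55–70 of 100 columns rather than close to the planted 10,
while recovery of the planted columns themselves is excellent (median
recall 0.9–1.0 over 5 seeds at population 20, 50 iterations). Each
feature block is selected independently; fusion is columnwise
concatenation (block a's columns first, labels must match).

## Classification and evaluation

The five shallow families use the hidden layouts the study's
environment implies: narrow (10), medium (25), wide (100), bilayered
(10, 10), trilayered (10, 10, 10), ReLU hidden activation, softmax
output. The package standardizes features and trains with L-BFGS
(deterministic under seed at these sizes). Metrics follow the tables'
conventions: percentages on 0–100, macro averaging, macro one-vs-rest
AUC on 0–1, FNR = 100 − macro recall, generalized (Gorodkin) multiclass
MCC, Cohen's κ; a class never predicted contributes precision 0
(logged). All formulas are cross-checked against brute-force
confusion-matrix arithmetic on 200 random instances.

The comparison t-test rounds μ and σ to 4 decimals before forming
t = √N·μ/σ — reproducing the published arithmetic chain exactly
(0.5/0.4183 → t = 2.6728 against ±2.776 at df 4) — and reports the
full-precision value alongside. σ = 0 is flagged degenerate with
t = +∞.

## Synthetic data

The image generator emulates just enough structure for the pipeline to
be testable: per class a distinct geometric motif (filled ellipse ≈
abdomen, ring ≈ skull, bright bar ≈ femur, none ≈ "no plane") under a
fan-shaped sector mask, with multiplicative Rayleigh speckle
(unit-mean, σ = 1 before normalization) and per-image jitter of motif
position (±10%) and scale (±15%). It does not attempt real anatomy,
acoustic shadowing, or clinical calibration — passing tests show the
pipeline's machinery works on separable speckled imagery, not that it
meets clinical performance.

The planted feature generator emulates GAP deep features with known
ground truth: noise columns are standard normal; informative columns
are *class-selective* — column j is elevated by `effect_size`
within-class standard deviations for exactly one class, assigned
round-robin (default 6 classes, matching the six-class dataset). This
mirrors how GAP channels behave (individual channels respond to
individual classes) and, unlike columns that all separate every class
at once, keeps every informative column individually load-bearing: with
10 independent all-class columns at effect 2 the wrapper task saturates
(hold-out error 0 for nearly any mask) and selection quality would be
unmeasurable. Ground truth is recoverable per column by a one-way
F-test at effect ≥ 2, n = 300, which underwrites the recovery
benchmark.

## Pipeline

`run_full_pipeline` executes the five experiments (raw block 1, raw
block 2, selected 1, selected 2, fused) and the t-test between two
classifier families, writing every artifact (split indices, loss
traces, feature CSVs, selection JSON, run report) under the output
directory. Seeds derive deterministically from the global seed per
stage. Two synthetic entry points exist: image-level (trains both
width-scaled CNNs; exercises every stage) and feature-level (two
planted blocks stand in for the CNNs' features; used to benchmark the
selection-fusion-classification chain under known ground truth).

Desk-scale problem sizes used by the test suite: 4 classes × 50 images
at 64×64 for the image smoke run; 300×100 planted matrices for
selection benchmarks; population 20 with 50–200 iterations for the
optimizer.

## Known limitations

- The published parameter totals are unreachable from the published
  layer lists (see Architectures); parameter-budget comparisons against
  ResNet-18/50 do not hold for the faithful builds.
- The 3-block network (deep, batchnorm-free, mostly 1×1 spatial after
  the stem at small inputs) trains unreliably on very small image sets
  (~100 training images): runs are bimodal between convergence and a
  slow-descent basin. The fusion-quality benchmark therefore runs on
  planted features, where both blocks are controlled; the image smoke
  run asserts completion, determinism and width bookkeeping.
- Selected widths exceed the planted support (see IGNDO); the
  threshold rule, not the search, sets that floor.
- The engine is single-threaded numpy; full-size (224×224, width 1.0)
  training is out of scope by design.
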