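# Methods

This note documents the models, the synthetic data, and the numerical
choices behind the package, in the order a user meets them.

## Problem and label transformations

The task is multi-label prediction of three chronic diseases —
hypertension (H), diabetes (D), fatty liver (FL) — from 62 numeric
physical-examination features per person (4 basic items, 26 blood-routine,
12 urine-routine, 20 liver-function items). Two standard problem
transformations are supported:

* **Label powerset (LP).** The 2³ = 8 possible label combinations become
  the classes of one 8-way classifier. The class order is fixed as
  {000, 100, 010, 001, 110, 101, 011, 111} → {0, …, 7}, i.e. singles
  before pairs, H before D before FL within each block. All encoding and
  decoding in the package uses this order.
* **Binary relevance (BR).** Three independent binary classifiers, one per
  disease, sharing nothing but the input features.

Label dependence is quantified by the Pearson product-moment correlation
between the 0/1 label columns, which for binary variables equals the phi
coefficient of the pairwise 2×2 table. In the cohorts this package
emulates, that dependence is weak: the largest pair (H, FL) has phi 0.24.

## The group block and GroupNet

The classifier is a small 1-D convolutional network whose core unit, the
*group block*, is parameterised (L, N₁…N_L, j):

* L consecutive grouped convolution layers. Layer i's kernels are split
  into N_i independent partition units; each unit convolves only its
  1/N_i share of the incoming channels (kernel size 1×3, stride 1, 'same'
  padding, activation after every convolution).
* j trailing *cluster* convolutions with 1×1 kernels that remix feature
  maps across all groups.

For two consecutive layers with m and n kernels and an even G-way split,
the second layer holds G·(m/G)·(n/G)·k weights against m·n·k ungrouped —
exactly 1/G of the parameters. The package verifies this by enumerating
the weight tensors of built blocks.

One boundary case is forced by the data: the first grouped layer sits on
a single input channel (the 1×62 examination vector), where channel
splitting is impossible. Its partitions therefore each convolve the whole
input, the grouping is organisational, and the parameter saving starts at
the second layer — consistent with the two-consecutive-layer form of the
reduction above.

The full network is six layers: input (1×62) → group block → max-pooling
→ dropout → fully-connected → softmax. The LP variant ends in one 8-way
softmax; the BR variant is three disjoint copies, each ending in a 2-way
softmax (per-head argmax ≡ thresholding the positive probability at 0.5).

Defaults: block {2, 2, 2, 1} with 32 kernels per grouped layer and 32
cluster channels, pool 2, dropout 0.5, 64 fully-connected units, tanh.
The block notation and the training recipe are fixed by the study this
package operationalises; the channel widths and FC size are not legible
from its figures, so they are package defaults chosen to be small enough
for single-CPU training while leaving ample capacity for the synthetic
signal, and all are exposed in `NetworkSpec`.

The network engine is a compact NumPy implementation (grouped 1-D
convolution via im2col, reverse-mode gradients, inverted dropout,
Adam/SGD) in `groupnet.nnet`. Everything is float64 and seeded, which
makes fitted weights bit-reproducible on one thread; the convolution
forward/backward passes are tested against direct-loop oracles and finite
differences.

## Loss family

All losses are functions of p, the probability the softmax assigns to the
true class:

* cross entropy CE(p) = −log p;
* focal loss FL(p) = −(1−p)^γ log p with focusing parameter γ ≥ 0. The
  modulating factor (1−p)^γ down-weights well-classified records; γ = 0
  recovers CE exactly (tested to 1e−12).
* correlated loss, for the BR variant only: head k's objective is its own
  (main) loss plus the other two heads' losses weighted by the pairwise
  label correlations, CL_k = loss_k + Σ_{i≠k} α_{ki}·loss_i. CL1 builds
  the terms from CE, CL2 from FL. α is estimated as the PMCC matrix of the
  *training* labels only (no test leakage); a flag substitutes |α| for
  cohorts with negative correlations (the default uses the raw values, as
  every pair in the emulated data is positive).

Joint training optimises Σ_k CL_k per batch. Because the three heads have
disjoint parameters and α is symmetric, the exact gradient with respect to
head k is (1 + Σ incoming α)·∇loss_k; the training loop applies this
scaling analytically, and an acceptance test verifies it against central
finite differences of the summed objective. Setting α to the identity
reproduces three independent BR trainings batch for batch. Probabilities
are clipped below at 1e−7 before the log; batch reduction is the mean;
the last partial batch is kept.

## Training recipe

`TrainConfig` defaults to the selected recipe: learning rate 0.002, 20
epochs, batch size 128, Adam (conventional β₁ = 0.9, β₂ = 0.999), dropout
0.5, tanh, γ = 2. There is no early stopping and no validation split: the
model trains a fixed number of epochs and is scored on the held-out 30%;
performance is expected to degrade from over-fitting well beyond 20
epochs. SGD is available for comparison and needs roughly an order of
magnitude more epochs to approach Adam's training loss. A NaN/inf batch
loss aborts with a learning-rate hint rather than continuing silently.

The 70/30 split is stratified on the 8 LP classes (several classes occupy
only ~1% of records, so a simple random split can starve them in either
part); each stratum lands within one record of the 70% target, a
singleton stratum goes to training with a warning. Features are z-scored
with training-row statistics (clinical features have wildly different
units; the scaler is persisted as JSON and applied unchanged to test
rows). The `sweep` harness retrains one model per grid point over the
seven tunable dimensions (epochs, learning rate, batch size, kernel size,
dropout, activation, γ) and tabulates test metrics, sorted by weighted F1.

## Evaluation

Both variants are scored on the same 8-class surface; BR decisions are
recombined into an LP code first. From one-vs-rest counts TP_i, TN_i,
FP_i, FN_i and support proportions k_i (l = 8 classes):

* accuracy = (1/l) Σ_i (TP_i+TN_i)/n — the macro one-vs-rest binary
  accuracy;
* weighted precision / recall / F1 = Σ_i k_i · (per-class value), with a
  never-predicted class contributing precision 0 (flagged with a warning);
* subset accuracy = fraction of records with the exact combination right,
  reported alongside because the two accuracy notions are far apart at
  l = 8.

Two exact identities are worth knowing and are tested. Over all 8
classes, weighted recall equals subset accuracy (Σ k_i·TP_i/support_i =
Σ TP_i/n). And every wrong record contributes exactly one FP and one FN
across the 8 one-vs-rest problems, so the macro accuracy is an affine
rescaling of subset accuracy: accuracy = 0.75 + 0.25·subset_accuracy.

One commonly repeated claim about the weighted F-score does **not** hold
in general: that it is bounded above by both weighted precision and
weighted recall. Per-class F1 is the harmonic mean of P_i and R_i, which
lies *between* min and max of the two, so the support-weighted sum can
exceed either average (minimal counterexample: two records, true classes
(0, 1), both predicted 0: weighted F1 = 1/3 > weighted precision = 1/4).
On confusion patterns produced by reasonable trained classifiers the
bound usually holds empirically, but the package's acceptance checks
measure and report the violation on random predictions rather than
asserting the claim.

## Synthetic cohorts

No public cohort with this schema exists, so `groupnet.simulate` draws
one with the reported statistical structure:

* **Labels** come from a latent Gaussian copula. For each disease pair,
  `solve_latent_correlation` finds (by bracketed root-finding on the
  bivariate-normal orthant probability) the latent correlation ρ such
  that thresholding at the prevalence quantiles yields the target phi to
  1e−4; a target outside the Fréchet bounds for the margins raises with
  the feasible interval. The pairwise ρ's are assembled into a 3×3
  matrix, repaired by eigenvalue clipping if needed (repairs beyond
  Frobenius distance 0.05 are refused), and thresholded samples give the
  labels. This is the minimal mechanism matching the two things known
  about the real labels: their margins and their PMCC matrix.
* **Features** are linear mean shifts on a standard-normal baseline:
  x = N(0, I) + Σ_d y_d·effect_d + N(0, noise_sd²·I).

Defaults define the emulated study conditions: n = 20,000; prevalences
(0.35, 0.05, 0.50) — fatty liver balanced, hypertension moderate,
diabetes rare, which puts the isolated-diabetes LP cell near 1% and the
normal + H∧FL cells near 60% of records, matching the reported skew;
target phi (H,FL) = 0.24 as the maximum pair, with (H,D) = 0.15 and
(D,FL) = 0.10 chosen below it; noise_sd = 1; and 12 affected features
per disease at 0.8 baseline-SD each, placed in the clinically natural
groups (H in basic vitals + early blood items, D in later blood + urine
items, FL in the liver panel). With these effects a class-weighted
linear probe exceeds 0.75 balanced accuracy per disease, so the
training module has real signal to find.

What the generator does **not** emulate: real marginal distributions of
laboratory values (reference ranges, skew, heavy tails), nonlinear or
interactive feature–disease mechanisms, measurement missingness
structure, and any dependence beyond pairwise label correlation. Passing
tests therefore demonstrate that the pipeline recovers structure it is
built to represent, not clinical-grade performance on hospital records.

## Problem sizes and tolerances

Deliberate choices, stated once: moment-recovery checks use n = 10⁵ over
3 seeds (prevalence tolerance ±0.01, phi ±0.02); the end-to-end learning
check trains both variants on one n = 20,000 cohort with the default
recipe and requires the BR-CL2 model to beat the majority-class subset
accuracy by ≥10 points and to stay within 2 points of the LP variant;
loss identities are checked to 1e−12, the metric oracle to 1e−9, the
gradient-scaling identity to 1e−6 relative against central differences
(ε = 1e−5 on float64). Degenerate inputs have defined behaviour: constant
feature columns are centred but not scaled; a constant label column makes
phi undefined and is reported as NaN in summaries but is an error where a
correlation is required; never-predicted classes take precision 0; pooled
length < 1 and indivisible channel counts are configuration errors that
name the offending layer.
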