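# Methods

## Problem setting

After CAR-T cell infusion, cytokine release syndrome (CRS) is graded daily
from 0 to 4; grade ≥ 3 is *severe* and clinically urgent. The package
predicts, for every patient-day, the probability that the patient will be in
severe CRS 1, 2 or 3 days later (the *lead time*), from up to 42 daily
laboratory factors organised in four panels: coagulation & tumor load (9),
blood routine (10), biochemistry (16) and cytokines (7). Because CAR-T
cohorts are small, the model is pretrained on a larger related cohort
(COVID-19 patients, who show a comparable cytokine-driven inflammatory
response) and fine-tuned on the CAR-T cohort with most of the network
frozen.

## Network

Daily factor vectors are embedded by a learned linear map (`n_features ->
d_model`) plus absolute positional embeddings, then processed by a temporal
U-Net whose processing unit is the MFCF block: multi-head self-attention, a
feed-forward module, a depthwise temporal convolution module
(depthwise conv -> SiLU -> pointwise conv), and a second feed-forward
module. Every sub-module `m` uses the post-LayerNorm-then-scaling residual
form

    y = LayerNorm(x + m(s ⊙ x))

with a learnable per-channel scale `s` (initialised to 1) on the sub-module
input. There is no pre-LayerNorm anywhere and no Macaron half-step
feed-forward pair. The U-Net encoder halves the sequence length
`unet_depth` times with a stride-2 depthwise convolution (odd lengths are
zero-padded and cropped back on output); the decoder upsamples by
nearest-neighbour repetition plus a pointwise convolution and *adds* the
same-resolution encoder feature map (skip connection). A pointwise linear
head produces per-day two-class logits; the softmax severe-class component
is the raw probability, thresholded at 0.5 for the binary call.

**Causality.** Each day's prediction consumes the full history up to and
including that day and nothing later: attention keys are restricted to
non-future positions, convolutions are left-padded, and the U-Net up-path
is shifted one step right so a coarse feature that pools days 2t and 2t+1
never reaches a day earlier than 2t+1. Without this, the factor values of
the label day itself would be visible to the model and the lead-time
structure of the task would be vacuous. A single-day-input variant (for
comparison with the sequence model) is obtained by scoring length-1
sequences; no separate code path is needed.

**Padding.** Batches pad sequences to a common length; padded positions are
canonicalised to zero at every stage and masked out of attention and the
loss, so the output at real days equals a forward pass on the truncated
sequence exactly (tested to 1e-10).

Default hyperparameters: `d_model` 64, 4 heads, 2 MFCF blocks per level,
`unet_depth` 1, convolution kernel 9 (patient stays average about a week,
so the speech-model default of 31 would exceed the sequence), feed-forward
expansion 4, dropout 0.1.

## Numerical core

The network runs on a small reverse-mode automatic-differentiation engine
over numpy (`prcrs.autograd`): a tape of `Tensor` nodes with broadcasting
arithmetic, batched matmul, reductions, slicing/padding/repetition, and
composed softmax/log-softmax/LayerNorm/depthwise-convolution. The model is
small (tens of thousands of parameters, sequences of a few dozen days), so
this keeps the stack dependency-light and bit-reproducible on CPU. All
gradients are verified against central finite differences in the test
suite (agreement ~1e-10).

## Training and transfer

Loss is mean two-class cross-entropy over labelled, unpadded days
(optional class weights), optimised with Adam (lr 1e-3, batch size 12,
150 epochs by default — the published recipe). The best epoch is selected
by validation macro F1 (AUROC selectable). Pretraining uses a mixture of
60% source (COVID-like) and 40% target (CAR-T-like) patient-days, sampled
as whole patients; fine-tuning copies the pretrained weights and freezes
the `embedding` and `encoder` parameter groups (encoder MFCF blocks,
downsampling stems and the bottleneck), training the decoder and head.
Frozen groups are verified bitwise-unchanged in the tests. All
randomness — shuffling, dropout, initialisation — derives from explicit
seeds; repeated runs are identical.

Patient-level 6:2:2 train/validation/test splitting (largest-remainder
apportionment) and patient-level 5-fold CV prevent trajectory leakage
between partitions. Hyperparameters are tuned one at a time
(coordinate-wise argmax over a candidate list, ties to the first
candidate), matching the published tuning procedure.

## Probability calibration

Raw network probabilities are converted to empirical severe-CRS
probabilities by rank matching. Held-out predictions are sorted by
descending probability and paired with their true severe flags (the
*baseline*). For a new probability `p`: find the baseline entry nearest to
`p` (ties toward the higher-probability position), take up to `k` entries
on each side (the matched entry included; truncated at the list ends), and
report the fraction of severe cases in the window. The per-side width `k`
adapts to the local density of the baseline: 10 for `p` > 0.8, 15 for
0.3 ≤ `p` ≤ 0.8, 20 for `p` < 0.3 (severe cases are rare, so high
probabilities are sparsely populated). Boundary values 0.8 and 0.3 fall in
the middle band. The matched entry is included so a one-entry baseline is
well-defined.

## Synthetic cohorts

No public patient-level data accompany the method, so the package ships a
generator that emulates the statistical structure the method relies on:

- days per patient: shifted Poisson, mean 7.4 (≈ 1497 patient-days per 202
  patients);
- daily grade: first-order Markov chain over 0–4 starting at 0, calibrated
  so ≈ 22% of target-cohort patients peak at grade ≥ 3 and severe spells
  last about two days; an optional `severe_target` resamples trajectories
  to hit a Bernoulli draw of that patient-level prevalence;
- factors: unit-variance Gaussians whose means rise linearly with the
  current grade, scaled per panel — cytokines 1.2, biochemistry 0.7,
  coagulation 0.5, blood routine 0.25 — so panel-ablation experiments
  reproduce the clinically expected importance ordering;
- missingness: completely at random at a configurable rate (default 10%);
  the imputation procedure, not the generator, is what the package tests;
- source cohort: the same process with a +0.3 additive shift on factor
  means and its own prevalence (30%), giving a related-but-shifted
  distribution for pretraining.

What the generator does **not** emulate: real laboratory units and scales,
inter-factor correlation structure, informative missingness, fever-based
CRS onset annotation, or treatment feedback (tocilizumab/steroids blunting
trajectories). Passing tests therefore demonstrate that the machinery
recovers the planted grade-conditional signal and that transfer helps under
covariate shift — not clinical-grade performance on real cohorts.

## Imputation

Missing values are filled with the median of the factor over all
patient-days sharing the same CRS grade, falling back to the cohort-wide
median when a grade group never observed the factor. As written the rule
uses cohort-global medians (mild leakage across splits); a strict mode
restricts the median computation to a training-row mask.

## Evaluation experiments

The test suite runs a scaled-down transfer study chosen to fit a single
CPU core: 200 source and 60 target patients, five seeds, model width 16
with one block per level, 25 epochs per phase. Fine-tuned models are
compared with from-scratch training on the target training split
(validation macro F1), and lead-time degradation (AUROC at leads 1, 2, 3)
is measured on an independent 300-patient synthetic evaluation cohort —
the 12-patient validation split of a 60-patient cohort typically contains
only a handful of severe days, making its AUROC too noisy to rank leads.

## Numerical conventions and edge cases

- Undefined precision/recall/F1 ratios (empty denominator) are reported
  as 0; macro F1 is the mean of per-class F1, not the F1 of macro P/R.
- AUROC gives ties half credit; AUPRC uses step interpolation (no
  trapezoid over precision).
- The paired t-test on fold-wise AUROCs returns (0, 1) for identical
  vectors and a signed-infinity limit with a warning when differences have
  zero variance but nonzero mean.
- Standard deviations in z-scoring are floored at 1e-8, so constant
  columns standardise to zero.
- Split sizes use largest-remainder apportionment (202 patients at 6:2:2
  give 121/41/40 — quotas 121.2/40.4/40.4).
- Grade transition matrices must be row-stochastic to 1e-9; generator
  percentages are rounded half-up to one decimal.

## Known limitations

- The numpy backend is CPU-only and single-threaded beyond BLAS; the
  default 150-epoch recipe on a full-size cohort takes minutes, not
  seconds.
- The positional-embedding table caps sequences at 128 days.
- The rank-matching calibration is a step function of the baseline; with
  small baselines the calibrated probability is coarse (multiples of
  1/window).
- Source/target feature spaces are assumed to share the 42-factor schema;
  a name-intersection adapter for mismatched schemas is out of scope.
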