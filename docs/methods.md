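# Methods

This note documents the model, the training and evaluation procedures, the
synthetic cohort generator, and the numerical and design choices behind them.

## The model

`pansurv` predicts a scalar log-risk per patient from two routinely available
inputs: a bag of patch embeddings extracted from the patient's H&E whole-slide
images, and a small clinical covariate vector (age, sex, tumor stage). A
cancer-type code conditions the final risk head, so one model serves a
multicancer cohort.

**Attention MIL.** All patches of all of a patient's slides are pooled into
one bag (the model emits one risk per patient, and pooling is the simplest
contract consistent with that). The N x D patch matrix is embedded to a slide
space of width `d_slide`, and pooled by gated attention — softmax over scores
`w'(tanh(EV) ⊙ σ(EU))` — into a slide summary H1. Attention weights are
exposed for heatmaps. Because the survival objective is rank-based, the
*polarity* of attention (whether high attention marks risk-elevating or
risk-lowering morphology) is not identified by the bag-level loss alone: any
monotone readout of the informative-patch fraction is an equally good
optimum, and in simulation the trained tilt flips sign across seeds. The AMIL
module therefore carries a per-cancer linear *instance-risk probe*, trained
with the same survival loss on its mean-pooled output — a linear Cox readout,
whose sign is identified — and a light pairwise term (default weight 0.3)
that encourages attention scores to rank patches the way the probe does
(probe values enter as constants). High attention then consistently marks
risk-elevating evidence, which is the property heatmap consumers assume.

**Cross-attention fusion.** H1 and the encoded clinical vector C are projected
by two symmetric two-layer MLPs into a shared latent space (1 x d). Attention
between two single vectors is degenerate (a softmax over one key), so each
embedding is reshaped into `n_tokens` sub-tokens (default 4) and multi-head
cross-attention (default 4 heads) is computed in both directions: clinical
queries attend over histology tokens and vice versa. The two attended
summaries are concatenated and linearly mapped back to 1 x d. Setting
`n_tokens=1` reproduces the degenerate single-vector reading.

**Cancer-aware expert routing.** The cancer-type one-hot passes through a
two-layer SiLU network with instance normalization to give a control token
(1 x d, zero mean, unit variance across features). Gate logits are a linear
projection of the token (a switch allows conditioning on the fused feature as
well); the patient's own-cancer logit receives an additive boost of ln K
(configurable), which guarantees the own expert survives top-k selection at
initialization while leaving room for cross-cancer sharing. Softmax gates are
restricted to the top-k experts (default k=2) and renormalized, so the risk
is a convex combination of expert outputs. The expert pool holds one
two-layer SiLU MLP per cancer type, applied to the channelwise concatenation
[fused ‖ token]. Two stabilizers keep routing interpretable: the gate
projection is zero-initialized (standard mixture-of-experts practice — the
boost alone sets the initial routing, so each expert starts specialized to
its own cancer and specialization can lock in), and the gate's learning rate
is scaled down (default 0.1x) so learned logits do not race past the boost
while the experts are still fitting.

## Clinical encoding

Fixed layout, M = 8: `[age/100, sex_female, sex_male, stage_I..IV,
stage_missing]`. Age is scaled to keep magnitudes O(1); stage has an explicit
missing slot because some cancers (e.g. lower-grade glioma) have no
conventional staging; missing age/sex encode as zeros with a missingness
mask. The encoding is total and deterministic.

## Objective

`L = L_cox + L_rank` over each accumulated batch.

* `L_cox`: negative log Breslow partial likelihood, averaged over events.
  Breslow's approximation handles tied event times. The average (rather than
  sum) keeps the term scale-comparable across batch sizes.
* `L_rank`: mean logistic surrogate `log(1 + exp(-(r_i - r_j)))` over
  comparable pairs (event_i = 1, t_i < t_j). A hinge alternative exists; the
  logistic form is smooth with bounded gradients.

Both terms are translation-invariant in the risks, so only risk *differences*
are learned. The auxiliary probe loss (same two terms on the probe's pooled
output, default weight 0.3) and the attention-anchor term complete the
training objective; both are internal to the AMIL design (see above).

**Gradient accumulation contract.** Batches are composed to balance cancer
types (per-cancer counts within one of the proportional quota). Per-patient
forwards may be staged in chunks, but Cox risk sets and ranking pairs always
span the whole accumulated batch; the loss and every parameter gradient are
identical to a joint full-batch computation (property-tested to 1e-5
relative error).

## Training

AdamW (decoupled weight decay, default 1e-2) with a cosine-annealed learning
rate: `lr(e) = lr_min + (lr - lr_min)(1 + cos(pi e / E)) / 2`, reaching
`lr_min` (default 0) after the last epoch. Stratified k-fold cross-validation
(per cancer type, shuffled then dealt round-robin) gives 4:1 train/validation
splits; out-of-fold predictions cover every patient exactly once. Optional
Polyak (EMA) weight averaging (per-step decay, e.g. 0.98) reduces the
variance of the final weights on small cohorts; it is off by default and
enabled in the small-cohort recovery studies. All randomness (splits, batch
composition, initialization) derives from explicit seeds; repeated runs are
bit-identical. All-censored batches are skipped rather than stepped, to avoid
optimizer-state drift from vacuous gradients.

The network is implemented on a small reverse-mode automatic-differentiation
engine over numpy arrays (`pansurv.autograd`); analytic gradients are
property-tested against central finite differences for every operator and for
the full model.

## Evaluation protocol

All metrics operate on pooled out-of-fold predictions, overall and per
cancer type.

* **Fold calibration.** Risk scores from different fold models are only
  identified up to monotone transforms (the losses are translation-
  invariant), so pooling raw scores mixes incompatible scales and deflates
  rank-based metrics — by 0.02-0.04 C-index in the bundled studies. The
  results surface therefore rank-calibrates each fold's risks to within-fold
  percentiles before pooling (`fold_rank_calibrate`); the low-level
  `aggregate_cv` keeps raw pooling as its default.
* **C-index** (Harrell): comparable pairs are (i, j) with event_i = 1 and
  t_i < t_j; risk ties count 0.5; identical-time double events are not
  comparable.
* **Time-dependent AUC**: cumulative/dynamic estimator on a grid of 4 evenly
  spaced times between the 20th and 81st percentiles of observed times, with
  inverse-probability-of-censoring weights from the Kaplan-Meier estimate of
  the censoring distribution (an unweighted variant is available); the
  summary is the unweighted mean over the grid. Grid times with no cases or
  no controls are dropped with a warning.
* **Kaplan-Meier**: product-limit estimator, Greenwood variance, 95% CI via
  the log-log transform, clipped to [0, 1].
* **Log-rank**: two-group test with hypergeometric variance, chi-square with
  1 df, two-sided.
* **Median-risk split**: high risk = risk >= median (standard sample median;
  for even n the mean of the two middle order statistics).
* **Paired bootstrap**: patients resampled with replacement, the same indices
  for both models; per-replicate C-indices give percentile CIs and a
  two-sided z-test on the replicate-wise difference. Replicates with no
  comparable pairs are redrawn and logged.
* **Mann-Whitney U** on per-fold scores: exact distribution for small untied
  samples (via scipy), midrank/asymptotic with ties.

## Synthetic cohort generator

The generator emulates the statistical structure the model assumes — a
patch-level morphology signal, a clinical signal, and cancer-specific
effects — with fully known ground truth:

* Patient of type k draws an informative prevalence p ~ Beta(0.2, 0.2) and a
  bag of N ~ U{20..60} patches; ceil(pN) rows are N(3 mu_k, I) (a 3-sd shift
  along a type-specific unit direction), the rest N(0, I).
* Clinical: age ~ N(62, 12) clipped to [20, 95]; sex ~ Bernoulli(1/2); stage
  uniform over I-IV.
* True log-hazard h = gamma_k p + beta_k' z, with z the *standardized*
  (age, sex, ordinal stage) triple — the usual convention in survival
  simulation, making ||beta_k|| the clinical effect size in log-hazard units.
  Default gamma_k = 2, ||beta_k|| = 1 with stage-dominant structure and a
  small per-type perturbation. The bimodal prevalence law and standardized
  covariates put the log-hazard sd near 1.3, for an oracle concordance
  (achievable ceiling, E[sigma(|dh|)] under proportional hazards) around
  0.78; a narrower prevalence law or unstandardized covariates would cap the
  ceiling near 0.72-0.74 and make recovery studies uninformative.
* Outcomes: event time T ~ Exp(lambda0 e^h) with lambda0 = 0.02/month;
  censoring C = min(Exp(lambda_c), tau) with lambda_c = 0.018, tau = 120
  months, giving ~30% censoring under the defaults. Exponential survival
  keeps every rate analytically checkable (e.g. P(event) =
  lambda0/(lambda0 + lambda_c) when h = 0 and tau = inf); a Weibull shape
  parameter would not change any rank-based quantity under proportional
  hazards.

What the generator does *not* emulate: spatial correlation between patches,
encoder-specific embedding geometry, informative censoring, cancer-specific
baseline hazards, or multi-slide patients with heterogeneous slides. Passing
recovery tests on this generator shows the pipeline can extract a
prevalence-plus-clinical hazard from feature bags; it does not certify
performance on real slides.

## Preprocessing

Otsu's threshold (argmax of between-class variance over all 256 candidate
bin thresholds; ties to the smallest) is applied to the saturation channel
of an HSV thumbnail (~32x downsample): H&E tissue is chromatic, glass is
achromatic. A grayscale mode (tissue = low luminance) exists. Constant
thumbnails have no valid threshold and yield a flagged all-background mask.
Tiling lays a stride-equals-size grid from the origin at the target
resolution (1.0 micron/px, the portable definition of "10x"); partial edge
tiles are dropped, and a tile is kept when its projected tissue fraction is
at least 0.25 (configurable). The patch encoder is a pluggable interface;
the bundled `StubEncoder` (a fixed random projection of mean patch color) is
deterministic and serves tests and pipeline validation, not feature quality.

## Heatmaps

Attention scores are percentile-rank normalized (min -> 0, max -> 1,
midranks for ties; a winsorized min-max mode exists), painted onto each
tile's footprint at a working downsample (default 32x), optionally smoothed
with a Gaussian approximating bilinear upsampling, and alpha-blended
(default 0.3) over the slide thumbnail with a perceptually uniform
colormap.

## Problem sizes in the bundled studies

The recovery studies run a deliberately small configuration — K = 3 cancer
types, 200 patients each, D = 32, d_slide = 64, d = 64, 15 epochs, batch 64,
lr 2e-3 with EMA 0.98, two initialization seeds averaged per fold — chosen
so the full 5-fold study completes quickly on one CPU while leaving the
recovery margins intact. The same code paths scale to the full-size
configuration (D = 2560, d_slide = 768, d = 256, batch 256, lr 1e-4,
20 epochs), which is the package default.

## Known limitations

* The training stack is single-process, CPU-bound, and sized for cohorts of
  hundreds of patients with D up to a few thousand; it is not a GPU trainer.
* Attention heatmap polarity is anchored by the instance-risk probe; with
  the anchor disabled, heatmaps remain valid saliency maps but their
  orientation is not identified.
* The time-dependent AUC estimator assumes censoring independent of
  covariates (KM-based IPCW).
* No early stopping or hyperparameter search is built in.
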