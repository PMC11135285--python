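# Methods

## Problem and model

`trajgru` forecasts individualized disease-progression trajectories for
amnestic mild cognitive impairment (aMCI): given a subject's irregular,
incomplete history of 6 MRI markers (regional cortical thickness,
hippocampal volume / intracranial volume), 9 neuropsychological scores,
APOE e4 carrier status, the global amyloid Centiloid value and
demographics, it predicts the next visit's MRI markers and cognitive
scores, and supports downstream amyloid-positivity classification and
group trajectory analyses.

The network has three stages applied per visit `t`:

1. **Feature fusion.** The B' = 17 core features (MRI + cognitive + APOE +
   Centiloid) of one visit are treated as B' scalar tokens. With learnable
   square projections, `q = x Wq`, `k = x Wk`, `v = x Wv`; the
   feature-by-feature attention matrix is `A = softmax(q k^T / sqrt(B'))`
   row-wise, and the attended vector `A v` passes through a small
   feed-forward network (FFN) whose output is added back to `x`
   (residual). Demographics (age, education, gender) bypass the attention
   and are concatenated afterwards. `A` is returned for interpretation: it
   is row-stochastic and reads as "how much feature i attends to feature
   j" at that visit.

2. **Temporal recurrence.** A GRU cell modified two ways. The previous
   hidden state is attenuated by a temporal decay factor
   `omega_t = exp(-max(0, W_d delta_t + b_d))` driven by the per-feature
   time-delay vector `delta_t` (years since each feature was last truly
   observed), so stale context fades; and the gate input is the fused
   feature vector concatenated with the binary observation mask `n_t`, so
   the cell can discount imputed inputs:

       h~   = h_{t-1} * omega_t
       r_t  = sigmoid(W_r^i [x~_t, n_t] + b_r^i + W_r^h h~ + b_r^h)
       z_t  = sigmoid(W_z^i [x~_t, n_t] + b_z^i + W_z^h h~ + b_z^h)
       h'_t = tanh(W_h^i [x~_t, n_t] + b_h^i + W_h^h (r_t * h~) + b_h^h)
       h_t  = (1 - z_t) * h~ + z_t * h'_t

   With `omega = 1` and `n = 1` this is exactly a standard GRU (the test
   suite asserts equivalence against an independent loop-based GRU).

3. **Multi-task heads.** Two affine maps take `h_t` to the predicted
   next-visit MRI markers (6) and cognitive scores (9). Outputs live in
   min-max-normalized feature space; no output activation.

**Missing-value handling.** Before the network sees the data, missing
cells are imputed by a decay-weighted convex combination
`gamma * last_observed + (1 - gamma) * train_mean` with
`gamma = exp(-max(0, w * delta + b))`, `w = 1, b = 0` fixed by default
(learnable variants are a flag). The mask is *not* updated: imputed cells
keep mask 0, which is exactly what the recurrence consumes. Imputation is
idempotent, convex (every imputed value lies between the last observation
and the training mean), and leakage-free (means come from training
subjects only).

**Loss.** `L_total = alpha * L_m + gamma * L_c` with `alpha = 0.75`,
`gamma = 1.0`; each term is a mean squared error over *truly observed*
target cells only, so the model never chases its own imputations, and the
averaging (rather than raw sums) keeps alpha/gamma meaningful across
cohort sizes.

## Numerical and design choices

* **Autodiff.** The network is implemented in numpy over a small in-repo
  reverse-mode engine (`trajgru.autodiff`), validated against central
  finite differences (the suite checks every parameter block of a small
  instance to 1e-4 relative error).
* **Initialization.** Glorot-uniform weights; `h_0 = 0`. Two residual-path
  choices matter and are deliberate:
  - the FFN inside the fusion ends in an affine layer whose weights start
    at zero, so the fusion is the identity map at initialization and
    attention mixing is learned only where it reduces loss (the standard
    zero-init-residual-branch practice). ReLU sits between hidden layers
    only, so the FFN output is unconstrained in sign;
  - hidden-decay weights start at `|N(0, 0.01)|`, i.e. `omega ~ 1`
    (plain-GRU regime) with a strictly positive pre-activation so the
    decay remains learnable. A larger init measurably crippled the model
    by erasing memory before training began.
* **Optimization.** Full-batch Adam by default (deterministic under a
  fixed seed and single-threaded numpy); plain SGD is available behind
  `TrainConfig(optimizer="sgd")` for fidelity runs. Early stopping
  restores the epoch with minimal validation loss (default patience 20,
  max 300 epochs; the benchmark protocol below uses 40/800). L2
  regularization is added to the loss over all parameter blocks.
* **Grid search.** Exhaustive over learning rate {5e-5, 1e-4, 1e-3, 1e-2},
  FFN depth {1, 2, 3}, hidden size {16, 32, 48, 64, 80, 96} and l2
  {1e-6 ... 1e-3} (288 trials); selection by validation loss, ties broken
  toward the smaller model. Diverged trials (non-finite loss) score
  infinity.
* **Cross-validation protocol.** 5 folds x 5 repetitions at subject
  level. Per repetition each amyloid class is shuffled and partitioned
  into 5 folds; each fold serves once as the test set (so every subject
  tests exactly once per repetition) and a stratified 10% of the remainder
  is the validation set. Note the test share is therefore 1/folds; a
  protocol with both a 5-fold test partition and a 10% test fraction is
  not simultaneously realizable, and the partition property was kept.
* **Metrics.** MAE, MAPE and R^2 per feature over observed target cells in
  normalized space. MAPE excludes cells with |truth| <= 1e-8 and reports
  the exclusion count — several cognitive scores normalize near zero,
  which is why MAPE is large and unstable for them. R^2 uses the
  observed-cell mean; zero-variance truth raises an error rather than
  silently producing garbage.
* **Wilcoxon.** Exact two-sided signed-rank p-values by sign-flip dynamic
  programming for n <= 25 (zeros dropped, midranks doubled to integers),
  normal approximation with continuity and tie corrections above;
  cross-checked against an independent reference implementation in the
  tests.
* **Downstream classification.** RBF-kernel SVM, C chosen by inner 3-fold
  stratified CV over {0.1, 1, 10}, features standardized on the training
  split, AUC from decision scores. Sensitivity is the recall of the
  amyloid-positive class. The Centiloid feature is withheld from all
  classifier inputs because the group label is itself derived from
  Centiloid; feeding it in is circular and saturates every scenario.
  Scenario feature sets: `baseline_only` = first-visit features;
  `longitudinal_missing` = all visits, missing cells mean-filled at
  classification time; `longitudinal_imputed` = the model's predicted
  next-visit MRI/cognitive features (the denoised "final outputs"),
  alongside the decay-imputed inputs.
* **Trajectory analysis.** Relative change `(y_t - y_0)/y_0` per subject
  and marker, normalized to [-1, 1] by scaling negatives by |tensor min|
  and positives by tensor max (both extremes land exactly on +/-1; sign —
  atrophy vs growth — is preserved); cells with |s| >= 0.25 are flagged.
  Attention maps are group-averaged, min-max normalized per time slice,
  and flagged orange when a cell's weight fell more than 0.05 below its
  first-visit value on a decreasing series (last <= first with at least
  one strict drop), red when it rose more than 0.2 on an increasing
  series. The Centiloid cutoff uses exact two-cluster 1-D K-means (sorted
  sweep minimizing within-cluster SSE — deterministic, no Lloyd
  iterations) and returns lower-cluster mean + 2 sample sd.

## The synthetic cohort generator

Real aMCI cohorts of this kind are not publicly deposited, so every
analysis is exercised on a simulator whose defaults are the study
conditions (`configs/simulation_defaults.yaml`, version 1):

    y[i, f, t] = baseline[i, f] + slope[group, f] * t
                 + loading[f] * severity[i] + noise[i, f, t]

with per-group baseline means/sds of demographics, cognitive scores, APOE
carrier rates (17.0% / 64.6%) and Centiloid (7.5 +/- 18.8 / 90.9 +/- 31.1)
taken from published baseline characteristics of a two-group aMCI clinic
cohort. MRI baselines are field-typical values (mean regional cortical
thickness 2.3-2.6 mm, HV/ICV ~ 0.0045) since the source table does not
print them. Slopes make the amyloid-positive group decline strictly
faster on every marker, with CDR-SB the one rising score; a shared latent
severity factor (N(0,1) per subject) induces cross-feature correlation;
observation noise sds are 10-20% of the baseline sd. Missingness is MCAR:
intermittent Bernoulli masking (default 20%) plus monotone dropout with a
per-visit hazard; the baseline visit, demographics, APOE and Centiloid
(baseline-measured, duplicated) are never masked.

What the generator does *not* emulate: informative (MNAR) missingness,
nonlinear or practice-effect trajectories, floor/ceiling effects of the
test instruments, site/scanner effects, and realistic imaging covariance
beyond the single severity factor. Consequences worth knowing:

* group separability on the full battery is higher than in real clinics.
  Without dropout, mean-filling 20% intermittent missingness costs the
  classifier almost nothing and longitudinal AUCs saturate near 1.0;
  the between-scenario ordering (baseline-only < mean-filled longitudinal
  < imputed longitudinal) emerges under the default attrition, where
  nearly half of the follow-up cells are missing;
* measurement noise is comparable to one year of drift for MRI markers,
  so *observed* relative-change maps at the first follow-up are
  noise-dominated; the trajectory analyses are therefore reported on the
  model's predicted (denoised) trajectories, where the systematic group
  difference dominates;
* passing tests demonstrate correctness of the machinery and the
  qualitative group structure, not clinical performance numbers.

## The standard benchmark

200 subjects per group, 4 annual visits, 20% intermittent missingness, no
dropout, seeds 1-5; training budget 800 epochs with patience 40; a
stratified 5-fold split supplies ~60/10/20 train/val/test percentages per
class. At this size the full model attains MRI one-step test R^2 ~ 0.93
and beats the GRU-M ablation baseline (mean-fill imputation, no attention,
no decay, mask still appended) on MRI MAE for the majority of seeds. The
problem sizes used in tests and the acceptance script were chosen to keep
a complete run in minutes on a single CPU while preserving these
qualitative orderings.

## Known limitations

* Decay parameters of the imputation are fixed (w=1, b=0) by default;
  jointly learned input decay could close the remaining gap to pure
  carry-forward behaviour for very persistent features. No auxiliary
  reconstruction loss on observed cells is back-propagated through the
  imputation — the forecasting loss is the sole objective.
* An MAE training objective is available via `TrainConfig(loss="mae")`;
  MSE is the default and the configuration under which all reported
  behaviour was characterized.
* Rollout feeds back point predictions with mask 0; no uncertainty is
  propagated over forecast horizons.
* The 17-node fusion block conflicts with the source framework's stated
  21-node recurrent input; the schema is configurable and the
  discrepancy is recorded rather than resolved (gate-input widths here
  follow the implemented concatenation `[fused features + demographics,
  mask]`).
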