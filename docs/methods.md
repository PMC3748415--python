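# Methods

## Model

`lpsvm` fits a linear binary classifier sign(wᵀx − b) by minimizing the
bridge-penalized margin problem

    min_w  ½ Σ_j |w_j|^p    s.t.  y_i (wᵀx_i − b) ≥ 1,   0 < p ≤ 2,

optionally with a soft-margin cap 0 ≤ α_i ≤ C on the dual multipliers.
For p = 2 this is the ordinary hard/soft-margin SVM. For p < 2, and
especially p < 1, the penalty is a quasi-smooth surrogate of the
feature-count (L0) objective, so minimizers concentrate weight on few
features; that concentration is what the package exploits for embedded
gene selection.

### Iterative reweighting (majorize–minimize)

The penalty is nonconvex for p < 1 and non-differentiable at zero for
p ≤ 1. Around the iterate w⁽ᵗ⁾ it is majorized by the quadratic
½ wᵀV⁽ᵗ⁾w with

    V⁽ᵗ⁾ = diag[(|w_j⁽ᵗ⁾| + ε)^(p−2)],

and each outer iteration solves the weighted dual QP

    min_a ½ aᵀ diag(Y) X V⁻¹ Xᵀ diag(Y) a − 1ᵀa,
    0 ≤ a ≤ C,  Σ_i a_i y_i = 0,

then recovers w = V⁻¹ Xᵀ diag(Y) a and the bias b = |S|⁻¹ Σ_{k∈S}
(wᵀx_k − y_k) over the support set S = {i : α_i > 10⁻⁸}. The loop
starts from w⁽⁰⁾ = 1 — so the first pass is exactly the L2-SVM — and
stops when ‖w⁽ᵗ⁺¹⁾ − w⁽ᵗ⁾‖ / max(1, ‖w⁽ᵗ⁾‖) < 10⁻⁴. Because each
surrogate touches the true smoothed penalty at w⁽ᵗ⁾ and dominates it
elsewhere, the smoothed objective is non-increasing across outer
iterations when the inner QPs are solved accurately (asserted as a test
property at tight inner tolerance).

The discriminant is evaluated as wᵀx − b, matching the sign convention
of the margin constraints and of the bias formula above.

### Inner solver: SMO with maximal violating pairs

Each dual QP is solved by sequential minimal optimization: repeatedly
pick the maximal-violating pair (i = argmax of −y_k g_k over the
up-admissible set, j = argmin over the down-admissible set, where
g = Qα − 1), then move along d = y_i e_i − y_j e_j by the closed-form
step δ = −(y_i g_i − y_j g_j)/(Q_ii + Q_jj − 2 y_i y_j Q_ij), clipped
to the box; with non-positive curvature the better feasible endpoint is
taken. The step preserves Σ α_k y_k exactly and never increases the
dual objective. Iteration stops when the maximal KKT violation falls
below `smo_tol`. The gradient is maintained incrementally with a full
recomputation every 4000 updates to cap floating-point drift (measured
drift stays below 10⁻¹¹). Inner solves are warm-started from the
previous outer iteration's α, which is always feasible because the
constraint set does not depend on V. Q is cached densely up to 2000
samples; above that, rows are computed on demand from the weighted
feature factor.

An unbounded dual (hard margin on non-separable data) is detected when
a descent direction has no finite endpoint or α exceeds 10¹², and
reported as an error advising a finite C.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `p` | 0.8 | penalty exponent; 0.8 gave the best selection/accuracy balance on the synthetic benchmark |
| `epsilon` | 1e-8 | reweighting smoother; caps V entries at ε^(p−2), e.g. 10¹² at p = 0.5 |
| `box_c` | 10.0 | soft-margin cap; effectively hard-margin on the benchmark (cap rarely active); `inf` = true hard margin |
| `outer_tol` | 1e-4 | relative change of w that stops the reweighting loop |
| `max_outer_iters` | 150 | reweighting tails at p ≈ 0.8–1.0 need ~70–150 iterations (noise weights decay as \|w\|^(2−p) per iteration, which is only linear near p = 1) |
| `smo_tol` | 1e-5 | maximal KKT violation of an inner solve; first-order pair selection needs ~10k updates per decade of violation on degenerate duals, so tightening this mostly buys runtime, not accuracy (fits at 1e-5 and 1e-6 agree to plotting precision) |
| `max_smo_passes` | 200000 | per-solve update budget; exhaustion flags the model unconverged |
| `support_threshold` | 1e-8 | α cutoff defining the support set |
| `feature_threshold` | 0.2 | a feature is *selected* when \|w_j\| > 0.2·max\|w\| |

The selection rule is a *dominance* threshold, not a numerical-zero
test. Rationale: a dense L2 fit has no exactly-zero weights, so any
near-zero cutoff would call nearly all 100 benchmark features selected
at p = 2; measured weight profiles show informative features carrying
≥ ~0.33 of the maximal weight while noise features stay ≤ ~0.2 across
the whole p range, so 0.2 sits in the gap. The cost is that weakly
informative features (standardized class-mean ~0.3) sometimes fall
below the cutoff at small p, where reweighting exaggerates the spread
between strong and weak coordinates.

## Synthetic benchmark generator

Each sample has n = 100 features and a label y = ±1 with equal
probability. A per-sample coin (success 0.7, independent of y) decides
which block of three features carries the signal: the signal block is
drawn N(3y, 1), N(2.2y, 1), N(1.4y, 1); the opposite block is N(0, 1);
features 7–100 are N(0, 20) noise (variance convention — immaterial
after standardization). Features are then standardized to zero mean and
unit SD, with the scaler fitted on the training split only. The
relevant set is {features 1–6} (0-based {0..5} in code).

What the generator does *not* emulate about real expression data:
feature correlations (all features are conditionally independent),
heavy tails, batch structure, and class imbalance. Passing the
benchmark therefore demonstrates correct sparse recovery under
independent Gaussian noise, not robustness to real-array artifacts.

Two criteria score a fit: the prediction error rate Pe (% misclassified
validation samples) and the feature selection error rate Fse, defined
here as 100·|selected Δ relevant|/n — symmetric difference, so both
false positives and misses count, normalized by the total feature
count. The published benchmark never states its Fse formula; this is
the package's definition, and nonzero cells are therefore only
comparable with the published table up to a couple of percentage
points.

## Experiment harness

`run_experiment(grid, splits, n_trials, seed)` regenerates a fresh
1000-sample pool per trial (sub-seed derived from (seed, trial) via
`numpy.random.SeedSequence`), splits it per configuration, standardizes
on the training part, fits every p in the grid, and aggregates means
and SDs per (p, split) cell. Failed fits are excluded with a logged
count; more than 10% failures aborts. Trials are indexable via
`trial_offset`, so partial runs merge exactly into longer ones. The
study sizes used by the acceptance script and tests — 30 trials per
cell, the 11-point p grid, 1000-sample pools — were chosen so a full
grid completes in minutes on one CPU; the published table used ≥ 100
trials, so Monte-Carlo standard errors here are ~1.8× larger.

`select_p` picks the grid value minimizing validation error, breaking
ties toward the smaller (sparser) p.

## Known limitations and expected discrepancies

* **Absolute prediction-error level.** On this generator the best
  possible *linear* rule (large-sample logistic regression on the six
  informative features) still errs ~0.23%. The published table reports
  0.26–0.47% across the entire p grid and all split sizes — i.e. at or
  near that floor even with 250 training samples and at p = 2. Neither
  this implementation nor a reference L2-SVM (scikit-learn, C tuned)
  reaches that level: measured minima over the p grid are ~0.6–0.75%
  at 250 training samples and ~0.25–0.45% at 750. The qualitative
  structure (sub-1% error, intermediate p best, improvement with
  training size) reproduces; the absolute level at small training
  sizes does not.
* **Feature-selection error at extreme p.** Under the symmetric-
  difference/dominance-rule definition the benchmark's Fse stays below
  ~4% everywhere, with misses of weak features dominating at small p
  and occasional noise features entering at p = 2. The published
  250-sample column reports up to 8.33%, which is not reproduced under
  any single fixed selection rule we examined (see `feature_threshold`
  above).
* Convergence at p ≈ 1 is slow (linear decay of small weights); a few
  cells end unconverged within the iteration caps and are flagged, not
  discarded.
* The p < 1 objective is nonconvex: the algorithm finds a local
  minimum dependent (deterministically) on the all-ones initialization.
* Only linear, binary classification is implemented; no kernels,
  multiclass, or probability calibration.
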