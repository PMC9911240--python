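# Methods

This note documents the models and procedures implemented in
`squirrelselect`, the choices made where the design was genuinely open, and
what the synthetic experiments do and do not establish.

## 1. The squirrel search optimizer

SSA is a population metaheuristic for box-constrained minimization. The
population of `N` position vectors is ranked by objective value at the start
of every iteration: the best `n_hickory` (default 1) squirrels are assigned
to the hickory tree, the next `n_acorn` (default 3) to acorn trees, the rest
to normal trees. Movement rules per iteration:

- every acorn squirrel glides toward the hickory squirrel;
- a random half (`floor(n_normal/2)`, re-drawn each iteration) of the normal
  squirrels glides toward a uniformly chosen acorn squirrel, the rest toward
  the hickory squirrel;
- the hickory squirrel does not move;
- every glide is `x ← x + d_g·G_c·(target − x)` unless a uniform draw falls
  below the predator probability `P_dp`, in which case the squirrel is
  relocated uniformly inside the bounds;
- all positions are clipped to the bounds componentwise (clamping, not
  reflection — the simplest contract that keeps the containment invariant
  testable);
- updates are synchronous: all moves read the positions as they stood at
  the start of the iteration.

The gliding distance is sampled from the aerodynamic model
`d_g = h_g/(tan φ · s_f)`, `tan φ = C_D/C_L`, with `C_L ~ U(0.675, 1.5)` and
`C_D = 0.60`; with `h_g = 8` and `s_f = 18` this gives `d_g ∈ [0.5, 1.1112]`
and glide multipliers `d_g·G_c ∈ [0.95, 2.11]` — steps that deliberately
overshoot the target about half the time, trading local precision for
exploration along the line through the mover and its target.

Seasonal monitoring computes, for each acorn squirrel `i`, the Euclidean
distance `S_c,i = ‖FS_at,i − FS_ht‖₂` to the hickory squirrel. When
`min_i S_c,i` falls below the shrinking threshold
`S_min(t) = 10⁻⁵ / 365^(t/(T/2.5))` (`T` = iteration budget), winter is
declared and each normal squirrel is relocated to
`FS_l + Lévy ⊙ (FS_u − FS_l)`, with the Lévy step generated by the Mantegna
recipe (stability exponent β = 1.5, conventional 0.01 step scale). Only
normal-tree squirrels are relocated, so elites survive winter.

The written SSA sources leave several points ambiguous; the package fixes
them as follows. The gliding-distance formula is read as a division
(`h_g/(tan φ·s_f)`) — the multiplicative reading produces steps two orders
of magnitude larger than any practical search box and cannot converge. The
seasonal constant uses the Euclidean (square-root) form, which preserves the
zero-at-coincidence property either way. Predator-present behavior is
uniform relocation. "Predator absent" is decided by `R ≥ P_dp` (the weak
inequality is fixed so forced-draw unit tests are deterministic; the choice
is measure-zero).

**Randomness contract.** One seeded `numpy` generator drives a run; every
stochastic draw consumes from it in the documented order (initialization
row-major; per iteration: acorn glides in ascending population index, the
normal-squirrel partition permutation, normal glides in ascending index,
then any Lévy draws). This makes runs bit-reproducible and lets the test
suite hand-unroll an iteration with a scripted stream.

Elitism (the best-ever objective value never increases) and containment
(positions never leave the box) hold by construction and are property-tested
over random objectives and seeds.

## 2. Wrapper feature selection

The selector runs SSA over `[0, 1]^D` (one coordinate per feature) and
binarizes each position with a fixed threshold of 0.5 on the
bound-normalized coordinate. An all-below-threshold position falls back to
the single largest coordinate (ties to the lowest index), so masks are never
empty. Fixed-threshold binarization (rather than a stochastic sigmoid
transfer) keeps the position→mask map deterministic, which makes elitism
meaningful at the mask level.

A mask is scored by cross-validation on the data given to `fit`:

    f(mask) = (1 − w)·error_term + w·|mask|/D

- classification: stratified 5-fold CV of the wrapped classifier (Gaussian
  naive Bayes by default, KNN optional); `error_term = 1 − mean accuracy`;
- regression: 5-fold CV of inverse-distance-weighted KNN;
  `error_term = mean MAE / IQR(response)`, normalized by the interquartile
  range so the term is scale-free and commensurate with the sparsity term.

The sparsity weight defaults to `w = 0.01` so predictive performance
dominates. The CV fold assignment is seeded once per selection run from the
run's stream: every mask therefore sees identical folds and the fitness is a
deterministic function of the mask. The selector returns the mask of the
best position ever visited, plus the per-iteration fitness trace.

Budget defaults: 30 squirrels × 60 iterations (≈ 1 800 evaluations with
caching of repeated masks). Measurements during development showed larger
budgets (up to 50×300) change the outcome little on the synthetic cohorts;
see §5.

## 3. Prediction models

Both wrapped models are implemented from first principles (library
implementations appear only as independent cross-checks in the tests).

**Gaussian naive Bayes.** Class priors are class frequencies; per-class
per-feature means and (biased) variances are floored at
`var_smoothing · max_feature_variance` (default `var_smoothing = 1e-9`) so
constant features keep likelihoods finite. Posteriors are computed in log
space and normalized by log-sum-exp; the decision is therefore stable under
feature scalings of 10⁶ and class-order permutations.

**K-nearest neighbors.** Exhaustive Euclidean scan; distance ties resolve
by the lower training index (stable sort). Classification is an unweighted
majority vote — voting ties go to the class of the single nearest
neighbor — matching the plain formulation; distance-weighted voting is
deliberately not implemented. Regression is the inverse-distance-weighted
mean of the k neighbor responses; a zero-distance query returns the mean
response of the exactly matching points.

Both models serialize to a flat key–value text format for reproducible
reruns.

## 4. Evaluation protocol and synthetic data

`run_experiment` repeats (default 5×) the cycle: stratified random 7:1:2
train/validation/test split (exact integer sizes, e.g. 70/10/20 at
n = 100) → wrapper selection on the training split only → model
hyperparameter choice on the validation split (`k ∈ {1, 3, 5, 7}` for KNN,
`var_smoothing ∈ {1e-9, 1e-6, 1e-3}` for naive Bayes) → a single scoring
pass on the test split. Metrics are the confusion-count quantities
(accuracy, precision, recall = TPR, error rate = 1 − accuracy) and, for
regression, the MAE in months. Precision with no positive predictions is
reported as a flagged null and excluded from means with a warning, never
silently propagated as NaN. The positive class is "survives ≥ 5 years".

The synthetic generator emulates a prognostic morphometric cohort: default
200 patients × 30 standard-normal features named in mean/SE/"worst"
triplets. A planted subset (default 5 features) is shifted by ±effect/2
(default effect 2.0 SD) according to a Bernoulli(0.5) survival label.
Survival months are `60 + 12·(mean of the informative features) + ε`,
`ε ~ N(0, 1 month)`, floored at zero — centred on the five-year boundary so
the binary task is non-trivial, with uniform coefficients `12/n_informative`
months per feature unit so the months scale does not depend on how many
features are informative and the regression signal is sign-aligned with the
label. Features are independent by default; an equicorrelation knob exists
but defaults to 0. There is no censoring model — survival time is treated
as a plain regression target — and no mean/SE/worst dependence structure:
the triplet naming is cosmetic, every feature is an independent draw. Tests
passing on this generator therefore demonstrate the mechanics of selection,
classification and calibration of the pipeline, not performance on real
correlated clinical morphometry.

Problem sizes used by the shipped experiments: classification pipeline at
n = 200, D = 30 with 5 repeats; regression at n = 300 (single repeat per
seed, 5 seeds); recovery at n = 200 over 10 generated cohorts; optimizer
benchmark at 10-D, 50 squirrels × 500 iterations.

## 5. Known limitations

- **Threshold-binarized SSA is a weak subset searcher.** Glide multipliers
  in [0.95, 2.11] overshoot past the elite, so a follower's mask usually
  equals the elite's mask after one move: of ≈ 1 800 fitness evaluations in
  a default selection run only ≈ 300 distinct masks are visited, and fresh
  masks (predator relocations) carry ~D/2 features. The search consequently
  struggles to reach the small masks that minimize the objective: a greedy
  forward/backward bit-flip search on the identical fitness finds strictly
  better and substantially sparser masks. Selected sets are reliably
  *enriched* for planted features (precision far above equal-size random
  masks) but typically retain extra noise features.
- **Small sparsity weights cannot resist CV overfitting.** At w = 0.01 with
  n = 200 and 5-fold CV, one cross-validated sample is worth 0.005 of
  fitness while a feature costs 0.00033; masks that memorize the fixed fold
  assignment (CV accuracy up to 1.0 with ~15 features) genuinely dominate
  the objective, so a stronger search makes support recovery *worse*, not
  better. Users who care about support recovery should raise
  `sparsity_weight` and treat the selected set as a ranking, not an oracle.
- The regression pipeline inherits both effects: with 10–16 selected
  features instead of the planted 5, KNN pays the usual
  curse-of-dimensionality price, and the test MAE lands around 2.5 months
  where the planted mask would achieve 1.6–1.9 against a 1-month noise
  floor.
- The optimizer itself is unconstrained single-objective only; no parallel
  evaluation; fitness functions must be finite everywhere in the box.
- Wrapper CV retrains the full model per fold and mask; costs grow linearly
  in folds × population × iterations. The brute-force KNN is O(n²·D) per
  fitness evaluation.
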