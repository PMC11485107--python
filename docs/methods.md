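# Methods

This note documents the models, the assessment metrics, the synthetic
cohort, and the numerical and design choices behind `clintrust`.

## Problem setting

One row per patient, numeric/binary admission risk factors, and a binary
6-month outcome (0 survival, 1 death; death is the positive class
throughout). The outcome is rare (~10%), so all performance reporting is
built on sensitivity, specificity and their geometric mean rather than
accuracy.

## GRACE score

The calculator transcribes the eight-variable GRACE point table (age,
creatinine, heart rate, Killip class, systolic blood pressure, elevated
cardiac markers, cardiac arrest at admission, ST-segment deviation).
Totals range from 2 (creatinine's lowest band scores 2, everything else
0) to 383.

Numerical conventions:

* **Bin edges.** Printed ranges such as "70–89"/"90–109" leave the
  half-unit gaps ambiguous; bins are implemented as lower-inclusive
  half-open intervals ([70, 90), [90, 110), …) so that each variable's
  bins partition its domain. "<70" is (0, 70); ">200" is [200, ∞).
  Per-variable points are then monotone step functions — nondecreasing in
  age, creatinine, heart rate and Killip, nonincreasing in SBP.
* **Units.** Cohorts store creatinine in µmol/L (the lab convention of
  the discretization table); the GRACE module converts to mg/dl by
  dividing by 88.4 and this conversion exists nowhere else.
* **High-risk threshold.** The binary high/low-risk cut-off on the total
  is a required configuration value with no default, and the comparison
  is strict (total > threshold → high risk). Dichotomization points are a
  clinical governance decision, not something a library should guess.
* **Dataset mapping.** Study cohorts rarely carry the exact GRACE
  variables; `GraceCohortAdapter` aliases columns (STEMI → ST-segment
  deviation, troponin → elevated cardiac markers) and binarizes a
  continuous column aliased onto a binary variable at `marker_threshold`
  (default 0.1, an uncalibrated convenience for synthetic data).

## Rule-based classifier

Three stages, mirroring a physician's reasoning:

1. **Rules.** Single-condition binary rules `if feature <cmp> threshold
   then death`. A rule whose condition does not hold predicts survival
   (the complement convention) — this is what makes "correctness" defined
   for every rule on every patient: a rule `albumin ≤ 25 → death` is
   *incorrect* for a patient with albumin 30 who died, and *correct* for
   one who survived.
2. **Correctness learning.** The N×K correctness matrix R (r_ik = 1 iff
   rule k's output equals patient i's outcome) is the multi-label target
   of a learner mapping risk factors to the subset of rules to trust for
   that patient. Default: binary relevance — one independent
   L2-regularized logistic classifier per rule, probabilities thresholded
   at 0.5; any estimator with the same `fit(X, R)`/`predict(X)` surface
   can be swapped in. A rule whose correctness is constant in training
   (always right or always wrong) gets a constant predictor, since a
   discriminative fit is undefined there.
3. **Aggregation.** With Q accepted rules, the mortality score is the
   fraction of accepted rules predicting death, thresholded *inclusively*
   at 0.5 for the final label. This is identical to majority voting among
   accepted rules, with ties resolved toward death. Q = 0 (every rule
   rejected) predicts survival — the majority class — and sets an audit
   flag on the returned score.

**Rule derivation.** In clinical deployment the rule set comes from
domain knowledge plus clinician validation; that workflow is out of scope
here and replaced by a reproducible threshold sweep: every
(feature, comparator, grid threshold) candidate is scored by training
balanced accuracy (SE+SP)/2 and kept if it meets `min_quality`
(default 0.6), sorted by quality with deterministic tie-breaks. The sweep
recovers planted thresholds exactly on noise-free synthetic cohorts.

## Trust metrics

**Stability.** For instance x with neighbors split by *predicted* label
into S⁺/S⁻, the measure is the normalized difference of Gaussian-kernel
mass, with bandwidth σ equal to the mean neighbor distance. Labels are
model predictions, not true outcomes: the metric captures the model's
consistency on similar inputs and is deliberately blind to accuracy (a
constant model is perfectly stable — which is why stability is always
reported next to the G_mean CI). Choices:

* neighborhood = all other instances (k = N−1); a k-nearest variant is
  available via the `k` argument;
* distances are Euclidean on z-scored numeric features (binary features
  enter as 0/1) — unnormalized clinical scales would let one variable
  dominate;
* σ = 0 (all neighbors coincide with x) assigns kernel weight 1, the
  continuous limit; a duplicate-only same-label neighborhood then scores
  exactly +1. For neighbors at a common *positive* distance d, σ = d and
  every kernel term is e^(−1/2), so an all-same-label neighborhood scores
  ≈ 0.607, not 1 — the ±1 endpoints are attained only at zero distance.
  The kernel form is evaluated as exp(−(d/σ)²/2) for robustness when σ is
  subnormal.

**Confidence.** The 95% CI of G_mean uses a nonparametric bootstrap with
B = 2000 resamples and the percentile interval. Resampling is *paired and
stratified*: (y_true, y_pred) pairs are drawn with replacement within
each true-outcome stratum, which guarantees both classes appear in every
resample so SE and SP are always defined. (With ~10% prevalence, naive
resampling loses the positive class in a nontrivial fraction of draws.)

**Interpretability.** Exact interventional Shapley values: the value of
a coalition S is the mean model output with features in S pinned to the
instance and the rest drawn from a background sample; φ is the
Shapley-weighted average of marginal contributions over all 2^(M−1)
coalitions per feature. Cost is 2^M model evaluations over the
background, so exact mode is limited to M ≤ 15. Attribution is computed
on the model's real-valued score (decision function or positive-class
probability) when available, hard labels otherwise. Feature importance
is mean |φ| over a seeded subsample of instances (default 50 instances ×
50 background rows); ranks are 1-based with ties averaged, so features a
model never uses share the bottom ranks through their zero importance.
Agreement with the clinical reference ranking is Spearman ρ. The
subsample is a pure function of (cohort, seed), so a model compared
against its own ranking yields ρ = 1 exactly — the defining property of
the reference row.

In a single-cohort trust report, `stability_std` is the per-instance
dispersion of the stability values within that cohort (a multi-run
protocol would instead report dispersion across runs).

## Performance harness

Repeated stratified holdout (default 10 runs, test fraction 0.3 — the
split ratio is a convention of this package — seeds
`base_seed … base_seed+n_runs−1`); each run refits the model and records
train and test SE/SP/G_mean; summaries are mean ± population std. The
predefined GRACE model has no training phase but is evaluated on the
identical splits. Pairwise method comparison applies the two-sided
Mann-Whitney U test in its normal-approximation dialect with tie and
continuity correction (for fully separated 10-vs-10 samples this gives
p ≈ 1.83×10⁻⁴; an exact-permutation test would give ≈1.1×10⁻⁵ — the
corrected approximation is the dialect standard statistical packages
print for these sample sizes).

## Harness models

Learner internals are delegated to scikit-learn; the harness fixes only
the configuration: z-scoring + logistic regression; clinical
discretization + categorical Naive Bayes; CART with max depth 3 (deeper
trees stop being readable); the rule-based classifier above. Because the
outcome is rare, logistic regression and the tree default to balanced
class weights and the NB to uniform class priors — without this every
learner collapses onto the majority class and sensitivity is near zero.
Each default is overridable through `ModelSpec.params`, and an optional
grid search (balanced-accuracy scored, 3-fold) is available via
`ModelSpec.grid`.

The clinical discretization maps age to six categories (edges 40, 50,
60, 70, 80), SBP to five (120, 130, 140, 180), heart rate to three (60,
100) and creatinine to three sex-specific bands (men: 61.9, 114.9
µmol/L; women: 53.0, 97.2). Bins are lower-inclusive (age exactly 40 →
category 2) with open-ended edge bins, so discretization is total and
monotone. Features without clinical bins are quantile-binned (numerics)
or passed through (binaries, small integer scales such as Killip);
categories unseen at fit time are clipped to the learned range. When no
`sex` column is available, sex-specific bins fall back to the male table
(`default_sex`).

Naive Bayes conditional probability tables are exposed per feature as
class-conditional category distributions; add-1 (Laplace) smoothing is
the default, and a near-zero `alpha` reproduces raw frequencies
(including structural zeros).

## Synthetic cohort

The generator emulates the class-conditional *marginals* of an ACS
admission cohort: mortality prevalence 150/1469 ≈ 10.2%, and per class
the means/IQRs of age (66.87 vs 77.49 years), SBP (135.05 vs 123.07
mmHg), heart rate (75.73 vs 84.02 bpm), troponin (41.54 vs 60.46),
maximum creatinine (112.28 vs 194.77 µmol/L), STEMI proportions
(0.36/0.46) and Killip-class means (1.35/2.53, realized by fixed
category weights (0.75, 0.17, 0.06, 0.02) and (0.25, 0.25, 0.22, 0.28)).

* Age, SBP and heart rate are Gaussian with sd = IQR/1.349, truncated to
  physiologic ranges.
* Troponin and creatinine are strongly right-skewed (their means sit near
  or above the 75th percentile), so they are log-normal with (µ, s)
  fitted by least squares on the relative errors of mean, Q1 and Q3. The
  three targets are *jointly unattainable* by any log-normal (the
  IQR-width/mean ratio exceeds the family's maximum), so the fit is a
  compromise: means are matched well, quartiles approximately.
* Cardiac arrest (required by GRACE, absent from the published
  summaries) is a rare binary, 2% survivors / 10% deaths — uncalibrated.
  Likewise sex (70% male) exists only to exercise sex-specific bins.
* Features are independent given the class. Real clinical variables are
  correlated (age with creatinine, Killip with heart rate, …); an
  optional Gaussian-copula mode accepts a within-class rank-correlation
  matrix, but no published correlation structure backs a default.

Consequently, passing calibration tests shows the generator reproduces
the intended *marginals*, not that downstream results transfer to real
cohorts: absolute stability values, CI widths and model rankings on
synthetic data are illustrations of the machinery, not clinical
findings.

`plant_rule_outcomes` overwrites outcomes with a known rule's output
(death if any planted rule fires) plus independent label flips at a
configured noise rate — the ground truth for rule-recovery tests.

## Problem sizes and determinism

The test suite works at deliberately modest sizes: cohorts of 400–2,000
patients for model behavior, 10,000 for generator calibration (age means
within ±1 year of target), 100,000 randomized neighborhoods for the
stability bound, bootstrap B = 2000 where interval geometry matters and
200–300 in smoke paths, Shapley oracles at M ≤ 5 via full permutation
enumeration. Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); cohorts, splits, bootstrap intervals and
Shapley subsamples are pure functions of their seeds.

## Known limitations

* Exact Shapley is exponential in M; no sampling approximation is
  included (M ≤ 15 enforced with a clear error).
* Global stability is O(N²) in memory/time via the full distance matrix;
  fine for cohorts of a few thousand, unsuitable for very large N.
* Single-condition rules only; conjunctive rules and the
  clinician-validation loop for rule sets are out of scope.
* The bootstrap "leave-one-out"/.632-style out-of-bag dialect is not
  implemented; the stratified percentile bootstrap is the single
  supported scheme.
* The three-level (low/intermediate/high) GRACE classification and the
  continuous GRACE 2.0 model are out of scope; only the binary mapping
  is provided.
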