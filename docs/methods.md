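# Methods

## Synthetic cohort model

Each individual i carries a constant (exponential) stroke hazard

    h_i = h0 * r_area(i) * exp(beta' z_i + gamma * 1[SBP_i > 160 and age_i > 65])

with standardized continuous covariates (age, systolic blood pressure)
and 0/1 indicators (current smoking, blood-pressure treatment, diabetes,
prior CHD) in `z_i`. The observed record is the competing minimum of the
event time `~ Exp(h_i)`, a covariate-independent dropout time
`~ Exp(c)`, and administrative censoring at the 9-year horizon. Constant
hazards give a closed-form truth, `p_i = 1 - exp(-9 h_i)`, used
throughout the tests; departures from a proportional-hazards model are
injected through covariate structure (the `gamma` interaction and the
area coding below), not through time-dependence.

Early censoring is non-informative by construction, matching the
assumption every survival estimator in the package makes.

### Key parameters (defaults, units, rationale)

| parameter | default | why |
|---|---|---|
| `prop_female` | 0.59 | two-sex cohort composition |
| `age_mean`, `age_sd`, `age_range` | 51.9, 10.6 y, [35, 74] y | truncated-normal age structure |
| `smoking_prev_male/female` | 0.677 / 0.032 | the dominant sex difference; with `beta=0.25` per smoker it reproduces the male excess incidence without a separate sex term |
| `n_areas`, `area_hazard_spread` | 10, 5 | area multipliers log-spaced to span a 5-fold range, geometric mean 1 |
| `beta` | age 0.80/SD, SBP 0.30/SD, smoker 0.25, BP-treatment 0.20, diabetes 0.45, CHD 0.40 | ~0.77 log-hazard per age decade and ~0.27 per 20 mmHg; conventional epidemiological magnitudes |
| `gamma_nonlinear` | -2.0 | log-hazard increment for the elderly-hypertensive subgroup (~2% of the cohort); see below |
| `base_hazard` | 5.73e-3 /person-year | calibrated by simulation (n=400,000) so 9-year incidence is ~9.2% in men, ~8.1% in women |
| `early_censor_rate` | 6.45e-3 /person-year | calibrated so ~5.4% of participants drop out stroke-free before 9 years |
| `diabetes_prev`, `chd_prev`, `bp_treatment_prev` | 0.08, 0.06, 0.12 | generator conventions; prevalences are kept high enough that every log-hazard coefficient is estimable to ±0.05 at n=50,000 (at ~3% prevalence the partial-likelihood standard error alone exceeds that) |
| `n_noise_features` | 12 | pure-noise covariates standing in for a wide questionnaire at desk scale |

### Why the nonlinearity is protective (gamma < 0)

The interaction subgroup (SBP > 160 mmHg and age > 65 y) already sits far
above the 10% screening threshold on its linear predictor alone. A
*positive* increment would raise its risk further — both models would
still call it high-risk, and no disagreement near the threshold would
arise. A *negative* increment makes a linear model systematically
overestimate the subgroup, which is precisely the structure that makes a
proportional-hazards model and a tree ensemble disagree on an
identifiable subpopulation. The sign is a modelling convention; what the
generator guarantees is a subpopulation on which linear and tree models
genuinely part ways.

### Geography: area code and urbanicity

Hazard multipliers are assigned to area codes 1..10 by a fixed,
seed-independent permutation: administrative codes carry no ordinal
meaning, so risk is non-monotone in the code. Models receive the area
code as a single numeric feature, plus a recorded `urban` indicator
marking the five areas in the upper half of baseline hazard — emulating
urban/rural site labels that explain part, but far from all, of
geographic risk variation. A linear model can use only the coarse
indicator; a tree model can partition codes. This, together with the
gamma subgroup, is what lets the GBT edge past Cox on discrimination at
desk scale and concentrates the meta-tree's Gini importance on blood
pressure, age and geography.

## Cohort preparation

* Splits are exact largest-remainder quotas (85 / 12.75 / 2.25%) applied
  within each sex, so printed fractions are reproduced exactly at any n.
  (Quota slicing per sex, rather than one cohort-wide random split
  followed by sex-stratified analysis, keeps small runs stable; the two
  coincide in expectation.)
* Follow-up windows are half-open `[t0, t1)` in years, avoiding
  double-counting of boundary events.
* Censoring asymmetry: stroke-free individuals censored before 9 years
  remain in the survival *training* data (a Cox likelihood handles them)
  but never enter binary-classification data and are excluded from every
  validation and test set, since their horizon outcome is unknown.
  Binary risk sets require being event-free and under observation at t0
  and observed through the window.

## Models

* **Cox**: lifelines partial-likelihood fit; baseline survival is the
  Breslow-type estimator at the covariate means, stored as a step
  function, giving `risk(t) = 1 - S0(t)^exp(beta'(x - xbar))` at any
  horizon and conditional window risks
  `1 - (S0(t1)/S0(t0))^exp(lp)`. An optional L1 penalty (lifelines
  penalizer, `l1_ratio=1`) provides LASSO-style shrinkage; the penalty
  weight can be chosen by cross-validated partial likelihood.
* **GBT**: scikit-learn `HistGradientBoostingClassifier` with
  deliberately conservative defaults (learning rate 0.05, 7 leaf nodes,
  ≥200 samples/leaf, 200 rounds, L2 = 1): cohort risk surfaces are
  smooth and low-dimensional, and the library defaults overfit training
  sets of ~1e4 rows with ~1e3 events badly (Hosmer–Lemeshow χ² in the
  hundreds).
* **LR / SVM / MLP**: standardized-input logistic regression is the
  linear binary reference; LinearSVC wrapped in isotonic calibration and
  a small MLP are optional plug-ins behind the same contract.
* **Fixed linear score**: externally supplied coefficients, centering and
  baseline survival. Recalibration freezes the coefficients and
  re-estimates centering and the baseline survival (Breslow estimator on
  the score's linear predictor), fixing calibration-in-the-large while
  preserving the published ranking; refitting re-estimates the
  coefficients by a Cox fit on the score's variable set.
* **Hyperparameter tuning**: stratified k-fold CV (k=5 by default) over
  an explicit grid, mean AUROC per candidate, ties resolved toward the
  earlier grid entry (order the grid simplest-first).

## Evaluation metrics

* **AUROC** is the Mann–Whitney concordance with half-credit for ties
  (rank-based computation, verified against a brute-force pair count).
* **Decile assignment** is by rank with ties broken by stable input
  order; group sizes differ by at most one. Quantile conventions differ
  across ecosystems, so the grouping is pinned down here.
* **Hosmer–Lemeshow** (binary): χ² = Σ (O−E)²/(n p̄(1−p̄)), df reported
  as G−2. Groups with degenerate mean prediction are ε-guarded and
  flagged.
* **Nam–D'Agostino** (survival): observed decile risk is 1 − KM(horizon)
  within the decile; χ² = Σ n(o−p̄)²/(p̄(1−p̄)), df reported as G−1; a
  Greenwood-variance denominator is available behind a flag. Groups with
  nobody under observation at the horizon are merged with a neighbor and
  flagged. With no censoring before the horizon the statistic reduces
  exactly to the Hosmer–Lemeshow form.
* **df conventions vs. null behavior**: the G−2 / G−1 conventions apply
  when the evaluated model was fitted in-sample. When probabilities are
  externally specified (as in the package's null simulations, where
  labels are drawn from the stated probabilities), no parameters are
  estimated and the statistic's null mean is ≈ G; the null-behavior
  tests therefore check the mean against the group count, with a wider
  band for the survival statistic because censoring slightly inflates
  the observed-risk variance relative to the binomial denominator.
* **Kaplan–Meier at a horizon** is computed by a compact product-limit
  routine (events ordered before censorings at tied times; Greenwood
  variance) so that it stays cheap inside 1000-fold bootstrap loops; it
  is verified against lifelines in the test suite.
* **Bootstrap**: percentile intervals (2.5/97.5) over resampled
  individuals, 1000 resamples by default; resamples on which a metric is
  undefined (e.g. single-class AUROC) are redrawn and counted. BCa was
  not used; the plain percentile method matches the package's reporting
  needs.

## Ensemble and screening

* High-risk means predicted 9-year risk **strictly greater than** τ =
  0.10 (the boundary case is unit-tested and τ is configurable).
* Meta-labels are deterministic: on a disagreement record the better
  model is the one whose label matches the realized outcome; exactly one
  side is better per record.
* The CART arbiter is implemented in-repo — node-level Gini bookkeeping,
  deterministic tie-breaking (lowest feature index, then lowest
  threshold, strict-improvement search) and JSON-serializable structure
  are part of the method's contract, not incidental backend details.
  Defaults: per-sex trees, `max_depth=4`, `min_samples_leaf=20`; leaf
  majorities tie toward Cox, the workflow's default model. A single-class
  disagreement set yields a flagged single-leaf tree.
* Gini importance of feature f is the total impurity decrease over nodes
  splitting on f, weighted by node size and normalized to sum to one.
* The ensemble rule passes the Cox label through untouched on the
  agreement set; only disagreement records can be overridden, so the
  override fraction is bounded by the disagreement fraction by
  construction.
* Screening metrics with zero denominators are reported as undefined
  (None), never as zero. Cohen's κ uses marginal-product chance
  agreement; two identical constant raters get κ = 1 by convention.

## Pipeline and reproducibility

The master seed fans out to stage seeds by hashing stage names (CRC32,
below 2³¹), so adding a stage never perturbs earlier stages' randomness;
the manifest records config hash, stage seeds and package version, and
identical configs produce byte-identical artifacts.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's standard desk-scale study conditions: marginal
checks and truth calibration on one 100,000-person cohort; the
replication study on ten 40,000-person cohorts (both sexes modelled in
each); coefficient recovery on ten 50,000-person cohorts fitted with the
generator's own design matrix; calibration null behavior from 500
replicates at n=10,000; the acceptance script runs one 100,000-person
cohort with 1000 bootstrap resamples.

## What passing tests do and do not show

The generator reproduces the *structure* the method needs — two sexes
with divergent smoking, censoring of the stated size, a >5-fold
geographic hazard spread, a subpopulation on which linear and tree
models disagree — and the tests show the pipeline's plumbing is exact
and its statistical behavior matches theory on that structure. The
generator does **not** emulate real questionnaire data: covariates are
complete (no missingness), hazards are constant in time (so
discrimination decays across follow-up windows only through risk-set
depletion, a ~0.004 AUROC effect per window at these sizes), there is no
measurement error or competing mortality, and absolute AUROCs (~0.72–
0.75 here) are not comparable to values attainable on richer real
feature sets. Conclusions about real cohorts require real data; what
transfers is the validated machinery.

## Known limitations

* Random survival forests are not bundled; the `RiskModel` contract
  accepts any object with `fit`/`predict_risk`, and RSF can be plugged
  in externally.
* The fixed-linear-score benchmark ships no published coefficient set;
  scores are supplied as configuration.
* The meta-tree sees the same feature matrix as the base models; no
  transformed or model-derived features (e.g. predicted risks) are added
  to it.
* Bootstrap CIs for the Nam–D'Agostino χ² resample individuals and
  re-form deciles per resample; decile membership is therefore not fixed
  across resamples.
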