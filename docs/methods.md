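# Methods

This note records the models implemented in `quitcost`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Study design being emulated

The package targets a two-group, multi-centre, individually randomized
smoking-cessation trial run in six EDs: ~488 control and ~484 intervention
participants, 6-month follow-up of 65.0% (control) and 72.5%
(intervention), CO-validated sustained abstinence near 4.1% vs 7.2%, and
heavily right-skewed 6-month healthcare costs (secondary care mean ≈ £1494
with a standard error of similar order). The synthetic generator's defaults
(`default_trial_config`) encode exactly these conditions; they are the
study conditions, not tuning knobs.

## Synthetic-trial generator

* **Covariates.** Age ~ truncated normal (40.5, 13.7) on [18, 90]; female
  ~ Bernoulli(0.38); FTCD dependence score ~ binomial(10, 0.5);
  other-smokers-in-household ~ Bernoulli(0.5); deprivation decile uniform;
  attendance-for-injury ~ Bernoulli(0.4). Site is uniform over the
  configured number of sites (a stratification label only — no site-level
  effect is simulated beyond the analysis treating it as a stratum).
* **Costs** are zero-inflated gamma per category and arm: a point mass at
  zero (no service use) plus a gamma for users. The family is a modelling
  choice — the emulated data report only means and standard errors, and
  SE ≈ mean implies heavy right skew, which small gamma shapes (0.18 for
  secondary care) reproduce. Zero-mass and shape defaults were fixed once
  on that reasoning.
* **Utilities** at baseline and 6 months have truncated-normal marginals on
  [−0.594, 1] (the floor of the common UK crosswalk value set), with the
  pre-truncation location solved numerically so the *post*-truncation mean
  hits the target (0.527/0.550 baseline, 0.634/0.660 at 6 months; SD 0.31
  back-calculated from the reported standard errors), tied across time
  points by a Gaussian copula at correlation 0.5.
* **Abstinence.** CO-validated abstinence is generated as a subset of
  self-reported abstinence (validated implies self-reported), each
  Bernoulli at its arm rate.
* **Missingness** is missing-at-random: lost-to-follow-up wipes every
  6-month field, with the logistic model
  `logit P(missing) = α_arm + βᵀx` in baseline covariates; α_arm is
  calibrated by root-finding so the expected follow-up fraction equals the
  arm target given the realized covariates. Defaults tilt missingness
  towards younger, more dependent smokers (β_age = −0.015, β_FTCD = 0.06 on
  the missingness log-odds — modest, plausible values fixed a priori). A
  2% sporadic item-missingness and 1% baseline missingness exercise the
  item-level paths.
* **Treatment cost** per intervention participant is the cost build-up
  itself (training and equipment totals spread over the arm, kit with
  probability 483/484, advice minutes ~ truncated normal (25.7, 7.3));
  control participants carry the £0.20 information card.
* **Broader sample**: optionally, non-randomized accompanying persons
  (default 35 when enabled) are appended with `is_randomized = False`,
  assigned to their index participant's arm.
* **Not emulated:** within-site correlation beyond the site label,
  visit-level longitudinal resource trajectories, informative (MNAR)
  missingness, and measurement error in CO validation. Passing tests on
  synthetic data therefore demonstrate the *machinery* (estimator
  correctness, coverage under MAR, determinism), not robustness to
  clustered or MNAR real-world data.
* Per-arm participant spending on NRT/e-cigarettes is not published (only
  an adjusted difference of about £45), so the generator's means (£40
  control, £85 intervention) are free values chosen to imply a gap of that
  order.

## Costing

Training cost is the exact sum of trainer-session costs (hourly × hours)
plus trainee opportunity cost (hourly × total hours × headcount); brief
advice is minutes × hourly cost / 60. The CO-monitor total is carried as
the input constant £276.30: the published figure is not exactly reproduced
by either straight-line or annuity depreciation at 3.5% over 5 years, so
recomputation is offered only as an explicit, convention-tagged operation
(`equipment_cost`), preferring fidelity to the printed total over guessed
arithmetic. Leaflet (£0.39) and bag (£1.47) go to every randomized
intervention participant (matching the per-participant presentation of the
cost table); the kit (£23.15) to recipients only. Resource-use counts must
be supplied in the unit-cost table's own unit (`unit_label`); monetary
outputs are kept at full precision internally, reported at 2 dp, and
rounded to the nearest pound (halves away from zero) only for headline
figures. The over-the-counter NRT price file is a synthetic placeholder
(flagged in its header) because the underlying price survey is not
redistributable.

## QALYs

A `ValueSet` must cover all 3125 EQ-5D-5L states and anchor 11111 at 1.0.
Official country tariffs are licensed, so the packaged default is a
synthetic linear set (utility = 1 − 0.05 × Σ(level−1)); any tariff can be
loaded from a (state, utility) CSV. QALYs are the trapezoid
`h(u₀+u₆)/2`, undiscounted over the 6-month horizon. Death is not modelled
within the trial window; mortality lives in the lifetime model.

## Missing-data machinery

* The deterministic outcome rule (missing ⇒ not abstinent) runs before any
  statistical imputation, so abstinence denominators are the randomized
  arm sizes.
* MICE-PMM: chains run separately per arm (`by_group`), site enters every
  equation as indicator variables, and each of the default 10 cycles visits
  the six follow-up variables in order, each regressed on all the others
  plus the complete baseline predictors (the standard
  everything-predicts-everything default; the emulated analysis lists its
  variables but not a per-equation predictor matrix). Chain length is a
  default of 10 cycles (unstated in the emulated analysis; 10 is the
  common practical choice), reduced to 5 inside bootstrap replicates for
  speed. PMM draws the Bayesian linear-regression parameters (scaled
  inverse-χ² variance, normal coefficients), matches each missing case's
  predicted mean under the drawn coefficients to observed cases' predicted
  means under the posterior mode, and copies a donor value uniformly from
  the k = 10 nearest; imputed values are therefore always members of the
  observed pool within the arm. Binary variables use Bayesian logistic
  regression; on separation the fit is augmented with two half-weight
  pseudo-observations at the mean design row (one per outcome), and an
  unresolvable separation raises.
* The number of imputations is the highest percentage of missing data,
  rounded up (`choose_m`), floored at 1; the pipeline caps it (default 10)
  to keep full runs in the minutes range — a cap, not a recommendation.
* Rubin pooling uses total variance = within + (1 + 1/m) × between and a
  t reference with Barnard–Rubin degrees of freedom when the complete-data
  df is supplied.
* MNAR pattern-mixture adjustment multiplies only imputed cells (tracked
  by the stored missingness mask): costs up by 10/20/30%, 6-month utility
  down by 10/20/30%, and the 3×3 combined grid.

## Incremental estimation

Costs are total payer-perspective costs (treatment + cessation support +
primary + secondary care; participants' own NRT/e-cigarette spending is
carried but excluded). The cost model is a gamma GLM with log link —
standard for skewed, positive costs (the treatment cost makes every total
strictly positive) — with arm, age, gender, attendance reason, FTCD,
household smokers, baseline healthcare costs and site; the incremental
cost is the recycled-prediction average marginal effect of arm (predict
everyone as intervention, everyone as control, average the difference), so
it lives on the pound scale required by the ICER; its within-imputation
variance is by the delta method. If the gamma fit fails the model falls
back to an identity-link gaussian fit and logs the switch. The QALY model
is linear in arm, age, attendance reason, FTCD, household smokers,
baseline utility, attempting a site random intercept (REML) with
fixed-site-effects fallback, logged. A generalized linear mixed model for
the gamma cost outcome is not available in the stack, so the cost model
uses fixed site effects directly.

Bootstrap uncertainty follows bootstrap-then-impute: each of B replicates
resamples participants with replacement within arm × site, imputes once,
refits, and contributes one (Δcost, ΔQALY) pair — exactly B pairs, from
which percentile CIs, the cost-effectiveness plane and the CEAC are all
computed from the same draw set. Inside replicates the QALY model uses
fixed site effects: the stratified resampling already propagates
between-site uncertainty, and per-replicate REML would add cost without
information. The impute-then-bootstrap alternative is not implemented.
The CEAC threshold grid is £0–£50,000 in £500 steps, covering the usual
£20,000–£30,000 decision range. The CI style for ratio-type quantities is
bootstrap percentile throughout.

Complete-case analysis reruns the same estimators on participants with
complete costs, utilities and 6-month smoking status. The broader-sample
analysis includes the non-randomized accompanying records in an otherwise
identical pipeline.

## Lifetime Markov model

States (smoker, ex-smoker, dead), annual cycles from the trial mean entry
age (40.5, single entry age by default) to age 90. Transition construction:
smoker death = background mortality × RR (capped at 1); quitting applies to
surviving smokers; ex-smoker death = background mortality; relapse applies
to surviving ex-smokers (constant annual probability by default); dead is
absorbing. Each cycle accrues smoker-occupancy × smoking-attributable cost
and occupancy-weighted utility, discounted at 3.5%/year with the first
cycle undiscounted (t = 0); no half-cycle correction (the plain reading of
an annual-cycle model; both choices are defensible and the difference is
second-order here). Treatment costs enter once at cycle 0, undiscounted.
Female and male sub-cohorts run separately (weights 0.38/0.62 by default)
because the mortality, cost and utility schedules are sex-specific, and are
summed.

The packaged parameter file is **synthetic**: Gompertz-shaped mortality,
age-banded smoking-attributable costs and utility weights of plausible
magnitude, RR of death 2.0, natural quit 2%/year, relapse 8%/year. The
real parameter tables behind the published lifetime results are not
redistributable, so the engine accepts any parameter file of the same
schema, and the lifetime outputs under the packaged defaults are
structural demonstrations, not estimates. The PSA draws beta distributions
for probabilities (moment-matched at modest effective sample sizes),
lognormal for the mortality RR and a mean-one gamma multiplier for the
cost schedule; invalid probability draws are resampled up to a cap.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; identical config + seed reproduces datasets,
  imputations, bootstrap draws and PSA draws bit-identically.
* The linear-regression draw in PMM ridge-stabilizes X'X (factor 1e-8 of
  its mean diagonal) against collinear designs; design matrices drop
  constant columns.
* Transition rows are validated to sum to 1 within 1e-12; cohort occupancy
  conservation is asserted to 1e-9 in tests; a 3-cycle trace is verified
  against exhaustive path enumeration.
* Test and acceptance problem sizes are scaled to the minutes range: null
  coverage uses 50 replicate trials of 300/arm with m = 5 imputations,
  parameter recovery uses 10,000/arm complete data, pipeline smoke tests
  use ~120/arm with a handful of bootstrap replicates. These sizes are the
  package's own verification choices; production analyses should use the
  full m from `choose_m` and B = 5000 bootstrap replicates.

## Known limitations

* Site is a stratification covariate inside imputation, not a random
  effect; no multilevel imputation model.
* No covariate selection or model diagnostics beyond convergence logging;
  standard errors for cost-per-abstainer ratios are not produced.
* Currency handling is a scalar multiplier (`UnitCostTable.scaled`), not an
  indexed inflation series.
* The lifetime model is a cohort model — no individual microsimulation, no
  disease-state expansion, and no re-derivation of smoking-attributable
  costs from episode statistics.
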