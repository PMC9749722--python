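# Methods

## The estimand and the estimator

The target is the marginal hazard ratio (HR) of an absorbing, staggered
intervention (benefit receipt) on mortality in an open cohort with
rolling entry and administrative censoring. Time is discrete in months;
all dates are floored to calendar months indexed from the study start,
and `admin_end` is the exclusive end of follow-up (observable months
`0 … admin_end − 1`).

The estimator is a marginal structural model fitted by inverse
probability of treatment weighting:

* **Initiation model (PS).** Discrete-time hazard of starting the
  benefit: logistic regression of the initiation indicator on baseline
  covariates plus a natural cubic spline of follow-up time `t`, fitted on
  each person's untreated months *plus the initiation month* (the
  initiation month supplies the 1-outcomes the hazard model needs).
  Persons already treated when their risk period starts contribute no
  fitting rows and carry probability 1 throughout. The spline knots sit
  at the 5/25/50/75/95th percentiles (linear-interpolation definition) of
  observed person-month times; the basis is the truncated-power natural
  cubic basis (linear beyond the boundary knots), with cubic columns
  rescaled by the squared knot span for conditioning.
* **Weights.** The monthly probability of the *observed* treatment state
  is PS in the initiation month, 1 − PS while untreated, and 1 after
  initiation. Multiplied cumulatively over months this is the denominator
  probability of the observed treatment history; the weight is its
  inverse. That text read literally ("weight = PS when receiving,
  1 − PS when not, multiplied over time") describes the denominator
  probability, not an inverse; inverting it is what makes the estimator
  an IPTW, and the literal cumulative probability is available behind
  `literal=True` for comparison. Weights are stabilized by default with
  a covariate-free, time-only initiation model in the numerator, so the
  mean weight is ≈1; truncation is off by default with an optional
  percentile clamp (`truncate_percentiles=(1, 99)`), and a diagnostic
  flags maximum stabilized weights above 10.
* **Outcome model.** Pooled logistic regression of the monthly event
  indicator on treatment and the same style of time spline (the
  discrete-time baseline hazard), with the weight entering as a variance
  weight and the variance estimated by a cluster-robust sandwich with
  clusters = persons. This weighted-GLM sandwich was verified numerically
  identical to the GEE independence robust variance. For monthly event
  probabilities well under 1% the pooled-logistic odds ratio and a Cox
  partial-likelihood HR (Breslow ties) agree within 1%, which the tests
  check directly.

Hazard ratios are non-collapsible, so the recovery target is not
`exp(true conditional log-HR)` but the **counterfactual oracle**: the
generator simulates two arms on shared baseline draws and common monthly
random numbers — everyone treated from entry versus never treated — and
returns the pooled person-month odds ratio, i.e. the exact MLE of a
discrete-time hazard model of event on treatment alone.

## The synthetic cohort generator

The generator emulates the registry setting the analysis assumes:

* rolling entry, uniform over the 60 calendar months (5 registration
  years), administratively censored at month 60, so mean follow-up is
  ≈2.5 years;
* baseline covariates: one binary (`male`, p = 0.49), one 3-level
  categorical (`education`: high/medium/low, 35/40/25%), one continuous
  standard-normal (`income_z`), each raising both monthly benefit uptake
  (logit effects 0.10; 0, 0.3, 0.6; −0.35) and monthly mortality (0.30;
  0, 0.25, 0.5; −0.25). These sizes were fixed at design time so that
  the unweighted and causal HRs differ by ≈0.14 — clear confounding —
  while propensity overlap remains realistic (maximum stabilized weights
  single-digit);
* monthly uptake hazard expit(−3.66 + effects − 0.015·t) ≈ 2.5%/month at
  baseline with a slowly declining time trend (≈75% ever treated over 5
  years); monthly mortality hazard expit(−6.21 + effects + 0.1·(q − 3) +
  β·treated) with deprivation quintile q and true effect β = log 0.8;
* 200 municipalities with rank-based deprivation quintiles, an
  independent primary-care-coverage tercile, and a per-municipality
  probability that a death goes unregistered, in which case the person
  *appears administratively censored at the study end* — exactly the
  bias the restriction analysis probes;
* per-person income, application year, and a small flagged-ethnicity
  indicator (1.5%) so each eligibility exclusion has something to act on;
* optional per-quintile treatment effects (`true_log_hr_by_quintile`)
  for stratified-analysis checks, and a `staggered_entry=False` switch
  that gives every person full follow-up (used by the closed-form
  binomial death-count check).

What the generator does **not** emulate: household structure, benefit
amounts, conditionality compliance, calendar-varying eligibility rules,
time-varying covariates, treatment discontinuation (0.33% in the real
cohort, so the exposure is modelled as absorbing), linkage error beyond
the death-masking mechanism, and any age dependence of the mortality
hazard. Passing tests therefore demonstrate that the estimators recover
known truth under the assumed structure (correct PS specification, no
unmeasured confounding, monthly discrete time); they say nothing about
robustness to model misspecification in real administrative data.

## Cohort building conventions

* Eligibility rules apply in a fixed order, each person counted under the
  first rule violated: death before registration; age > 100 at
  registration; standardized income > 300; flagged ethnicity;
  registration in the final month or death in the registration month.
  The last rule is the monthly-resolution version of "applied on the
  last day or died the same day" — day-level events are not representable
  on a month grid. A flag additionally drops persons whose benefit
  started in their registration month (a robustness variant).
* Income standardization multiplies by the ratio of the reference year's
  eligibility threshold to the application year's (reference = latest
  year in the table).
* Age windows are half-open `[low, high)`: the risk period starts at
  registration or on reaching `low`, and the month of reaching `high` is
  excluded. If treatment and death fall in the same month, the month
  counts as treated. Persons whose benefit started before their risk
  window are treated from `t = 0` and contribute no PS fitting rows.
* Unregistered deaths end the true risk period but not the observed one:
  the person-month expansion continues to the administrative end with no
  event, reproducing the under-reporting bias deliberately.

## Descriptive statistics

Directly age-standardized rates use Σ w_a d_a/n_a with the
weighted-Poisson variance Σ w_a² d_a/n_a² and a normal interval on the
rate scale by default; a log-rate variant is provided because the
published tables (with person-time in the tens of millions, hence
degenerate printed intervals) cannot discriminate between the two. With
the cohort's own person-time shares as the standard, the standardized
rate equals the crude rate exactly — an identity the tests assert.
Standardized mean differences use the usual two-proportion and
two-mean forms, and the Mahalanobis generalization over K − 1 levels for
multi-category covariates; this variant reproduces the published
categorical balance rows (0.166 for race, 0.104 for education) to 3
decimals, confirming it is the one used.

## Robustness procedures

* **E-values** use the VanderWeele–Ding transformation
  `E = RR* + √(RR*(RR*−1))` with protective estimates inverted first;
  the CI e-value uses the bound nearer the null and is 1 when the
  interval crosses 1.
* **Risk-set matching** is 1:1 greedy nearest-neighbour without
  replacement within each initiation month, ties broken by person id,
  caliper defaulting to 0.2 × SD of logit(PS) over pre-initiation
  person-months. Future initiators may serve as controls and are
  censored at their own initiation in the matched analysis, which is a
  conditional logistic regression on matched-set person-months.
  Under confounded uptake this matched estimator is attenuated relative
  to the counterfactual oracle — censoring controls at their own
  (risk-correlated) initiation is informative — which is consistent with
  the divergent matched results reported for the real cohort; the
  recovery test therefore runs under uncorrelated uptake, where the
  design is unbiased.
* **Covariate-adjusted fits**: an unweighted pooled logistic model with
  covariates (the discrete-time analogue of an adjusted time-varying Cox
  model), plus a true partial-likelihood Cox fit on start/stop intervals
  (two per person at most) used for the rare-event equivalence check.
* **Restriction** keeps persons in municipalities whose death
  under-reporting probability is below 0.5%. The planted-bias scenario
  used in tests sets a null treatment effect, makes deprivation raise
  uptake (logit +0.5 per quintile) but not mortality, and hides half of
  all deaths in the two most deprived quintiles: the full-cohort
  estimate is then spuriously protective for the one reason under study,
  and restriction removes it.

## Problem sizes and numerical choices

Simulation-based tests use 6 000–50 000 persons per replicate and 20
replicates for the headline parameter-recovery and restriction checks,
with the counterfactual oracle evaluated at 0.5–1 × 10⁶ persons; these
sizes put Monte-Carlo error comfortably below the tolerances asserted
(e.g. per-replicate SE ≈ 0.06 on the log-HR at n = 20 000, so the
20-replicate mean is known to ≈0.013). Point estimates in multi-replicate
tests are fitted without the sandwich variance, which does not affect
coefficients. GLM fits use statsmodels IRLS defaults; the PS design is
checked for separation via non-finite coefficients; percentile
definitions follow numpy's linear interpolation; duplicate spline knots
are collapsed with an error below 3 distinct locations; unseen
categorical levels at prediction raise by default (reference-level
fallback is opt-in).

## Known limitations

Conditional-on-covariates effects are assumed time-constant and shared
across persons (except the optional quintile gradient); censoring weights
are not implemented (administrative censoring only, as in the design
being emulated); the Cox path is a cross-check, not a primary estimator;
and the matched analysis inherits the informative-censoring caveat above.
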