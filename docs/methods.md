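# Methods

This note documents the models and procedures implemented in `che_gap`, the
conventions fixed where definitions in the field are ambiguous, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Indicator definitions and conventions

Catastrophic health expenditure (CHE) is flagged per household by comparing
out-of-pocket (OOP) health spending to a resource denominator. Four objective
denominators are implemented: total household expenditure (budget share,
threshold 25%), and three capacity-to-pay variants at a 40% threshold —
total minus actual food spending, total minus a *partial normative food*
standard, and total minus a *normative subsistence* standard (food + housing
+ utilities). A fifth, subjective indicator carries the household's own
yes/no rating that its OOP spending over the past year was too high to
afford.

Conventions fixed by this package (each is a configuration value or a
documented rule; defaults in parentheses):

* **Strict thresholds.** A ratio exactly at the threshold is not CHE, reading
  ">25%" and ">40%" literally. Ties are exact in floating point only when the
  inputs allow it; the tests construct such ties with power-of-two
  denominators.
* **Equivalence scale** (exponent 0.56). Household totals are converted to
  per-equivalent-adult amounts as size^0.56 wherever a normative standard is
  applied or averaged. Exponent 0 collapses the scale to per-household
  amounts.
* **Quantiles are type 7** (linear interpolation between order statistics),
  NumPy's default and the convention of most statistical software. All
  percentile windows are closed intervals, bounds inclusive.
* **Window non-emptiness.** In waves of roughly ten or fewer households both
  interpolated window bounds can fall strictly inside the same gap between
  adjacent order statistics, leaving the closed window empty. The estimator
  then selects the household(s) nearest the window midpoint, so it is total
  for any wave with at least two positive-total households. At realistic wave
  sizes this fallback never triggers.
* **Subsistence ranking variable** (`per_equivalent`). The subsistence window
  ranks households by total expenditure; because the standard itself is
  equivalence-adjusted, the default ranks by per-equivalent total. Ranking by
  raw total is available as `subsistence_ranking: raw_total` — the choice is
  under-determined by the verbal definition, and both paths are tested.
* **Degenerate capacity to pay.** A household with capacity to pay ≤ 0 is CHE
  if and only if it incurs any OOP at all. This is the stated rule for the
  normative-subsistence indicator and is extended to a zero denominator under
  the two food-based capacity-to-pay indicators, as the continuity limit of
  the ratio.
* **Partial-normative fallback tie.** A household whose total expenditure
  exactly equals its standard food spending takes the normative branch
  (denominator 0), reading "less than the standard" strictly.
* **Total expenditure includes the OOP item** (it is one of the summed
  expenditure items). Some international variants exclude it; with the
  itemized schema a user can reconstruct either convention.
* **Incidence denominator** (`oop_positive`). Incidence and discrepancy
  percentages are computed among households that incurred any OOP spending —
  those that sought care — with `all` available as a switch.

Normative standards are computed per wave on the post-exclusion sample,
before any regression-stage missingness handling.

## Cohort construction

Two exclusion rules are applied in order, with exact accounting (initial and
final counts per wave, count per rule, and the identity final = initial −
rule1 − rule2 enforced): respondents outside the survey's eligible 18–69 age
range; then households self-rating their health spending unaffordable while
reporting zero OOP, for which the objective and subjective indicators cannot
be compared. Records missing a gate field pass the gate and are handled by
per-model deletion.

Continuous covariates are cut into within-wave quantile groups ("x-tiles"):
tertiles for household size, gender ratio, proportion of non-working-age
members and provincial per-capita health budget; quintiles for per-capita
income. A value lands in group *i* when cutpoint(i−1) < v ≤ cutpoint(i);
ties at a cutpoint go to the lower group, making regrouping idempotent.
Waves with fewer distinct values than groups raise a degenerate-cutoff error
naming the variable and wave.

"Pairwise deletion" across models is implemented as per-model listwise
deletion: each model drops only rows incomplete on its own outcome and
covariates, so retained n varies by model. This is the only reading
consistent with per-model sample sizes differing by outcome.

## Discrepancy outcomes

Households with both flags observed form a 2×2 partition per wave and method
(both / neither / self-only / objective-only; percentages rounded half away
from zero to 2 decimals). Outcome **A** ("self-rated CHE without objective
support") is the self-rating restricted to objective-negative households;
outcome **B** ("objective CHE without self-rated backup") is one minus the
self-rating restricted to objective-positive households. Outside its
subpopulation an outcome is missing. A's prevalence equals
self_only/(self_only+neither) and B's equals obj_only/(obj_only+both), which
the tests cross-check against the 2×2 counts.

## Association models

Single-level maximum-likelihood logistic regressions (statsmodels `Logit`)
on the categorized covariates with the reference levels of the covariate
schema (smallest size, lower gender ratio, no care need, tertiary education,
highest income quintile, upper class, lower non-working share, employed,
urban, hukou-aligned, uninsured, lower health budget, eastern region, first
wave), plus wave dummies. Reported per term: adjusted odds ratio, 95% Wald
CI, two-sided p-value with stars at 0.1/0.05/0.01, plus model-level McFadden
pseudo-R², AIC = 2k − 2·loglik, and the deletion report. Crude odds ratios
use the same machinery with a single term. A continuous-form variant
substitutes the untransformed numeric variables for the x-tiled ones as a
robustness check. Indicator columns that are constant, or supported by fewer
than 5 rows, in a model's analysis sample are dropped and reported in
`dropped_terms` (the "cannot generate results" case in sparse
subpopulations); terms with |coef| > 15 or SE > 50 are flagged `fit_failed`
rather than allowed to pass as estimates.

**Single- vs multi-level choice.** A null logistic model with a province
random intercept, u ~ N(0, σ²), is fitted by integrating the marginal
likelihood with adaptive Gauss–Hermite quadrature: 25 fixed nodes, centred
at each province's posterior mode and scaled by the local curvature
(non-adaptive quadrature is badly biased once provinces hold hundreds of
observations, because the integrand is much narrower than the prior). The
intercept-only model depends on the data only through per-province totals,
so the fit is fast and fully deterministic. The latent-scale intraclass
correlation is ICC = σ²/(σ² + π²/3); single-level modelling is recommended
below the conventional 0.059, and the AICs of both null models are reported.
The implementation was cross-checked against an independent adaptive-quadrature
mixed-model fitter on simulated data (variance and AIC agreeing to five
decimals), and the tests verify recovery of a known variance chosen to give
ICC = 0.10 within Monte-Carlo error of a 31-cluster design.

## Synthetic-data generator

The generator emulates a repeated cross-sectional household expenditure
survey: by default 10 000 households per wave over four waves
(2013/2017/2019/2021) across 31 provinces partitioned into eastern/central/
western blocks. Monetary values are abstract currency units per year; waves
are analysed separately, so no deflation is applied. Mechanisms:

* **Income** is log-normal within three socioeconomic strata (30/50/20%
  low/middle/high, log-means 9.3/9.9/10.5, σ 0.40–0.45), per capita.
* **Non-health spending** is a consumption share (60–90%) of household
  income; the **food share declines with log income** (Engel curve, base
  0.42 at the low-stratum log-income anchor, slope 0.085 per log unit,
  household noise SD 0.06, clipped to [0.10, 0.78]); housing and utilities
  take normal-draw shares of the non-food remainder.
* **OOP health spending** is a three-part mixture: zero with probability
  0.33, otherwise a log-normal multiple of non-health spending — moderate
  (median ratio 0.055, σ 0.9, weight 0.57) or heavy (median ratio 0.50,
  σ 0.7, weight 0.10). The heavy component produces the catastrophic tail,
  including households whose capacity to pay under the subsistence standard
  is negative, so both the zero-OOP exclusion rule and the negative-CTP rule
  are exercised at defaults.
* **Self-rating** comes from a latent propensity: 8.5·(OOP burden ratio) +
  1.1·(low-SES index) + 0.35·(care-need count) − 3.1 + logistic noise. The
  low-SES index combines inverted within-wave income rank, low perceived
  class, low education and unemployment, so — by construction — poorer
  households are more likely to self-rate CHE at equal objective burden.
  This is the mechanism the association models are expected to recover
  (lowest-income AOR > 1 for outcome A), and parameter-recovery tests
  confirm they do.
* **Composition and covariates**: size 1 + Poisson(1.8) clipped to 9; female
  count binomial; care-need flags, non-working-age share, education,
  perceived class, unemployment, residency, hukou alignment and a six-level
  insurance variable drawn with stratum- or residency-dependent
  probabilities so every level of the covariate schema has support at
  defaults. An optional province random intercept (SD configurable, default
  0) induces clustering in the self-rating for multilevel exercises.
* **Missingness** is injected per field at configured rates (1–4% on income,
  education, class, insurance, hukou, unemployment; ≈12% of rows incomplete
  per model), never touching the wave, province and size keys. Missing
  values are empty fields in CSV.

Defaults were chosen once so that the generated survey operates in the
regime such surveys report — self-rated incidence near 30%, objective
incidence roughly 10–20% with the subsistence indicator highest and actual
food lowest, a ~2–3% unaffordable-with-zero-OOP exclusion and ~12% per-model
missingness.

What the generator does **not** emulate: survey design weights (the pipeline
is unweighted throughout), member-level rosters (composition is drawn in
summary form), healthcare utilisation and forgone care, price inflation
between waves, item-specific reporting error, and any calibration to a
particular country's point estimates. Passing tests therefore demonstrate
that the pipeline's logic is correct under a realistic data-generating
process, not that any real population has these rates.

## Determinism and problem sizes

Every stochastic step flows from a single integer seed (NumPy
`SeedSequence` spawning per wave and per stage); a fixed seed reproduces
tables, CSVs and JSON artifacts byte for byte. The acceptance script runs
the full pipeline at the default 4×10 000 scale and a 31-province × 1 000
ICC recovery; the test suite uses reduced sizes (hundreds to a few thousand
households) for unit and property tests and the full default scale for
parameter-recovery checks, sizes chosen so results are statistically stable.

## Known limitations

* Wald CIs and McFadden pseudo-R² are fixed conventions (the defaults of the
  major survey-analysis packages); profile-likelihood CIs are not offered.
* The random-intercept machinery covers the null (intercept-only) model used
  for the single-vs-multilevel decision; full multilevel covariate models are
  out of scope, consistent with the single-level recommendation the ICC
  diagnostic is designed to justify.
* Impoverishment-style indicators and survey-weighted estimation are not
  implemented.
* The subjective indicator is a single yes/no item; nothing in the package
  models multi-item financial-hardship scales.
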