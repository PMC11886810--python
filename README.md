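# che-gap

**Catastrophic health expenditure (CHE) by objective indicators and
self-rating, and the gap between them.**

`che_gap` is a Python package for analysts of household financial protection
in health. It computes household CHE by the four objective indicators in
common international use, carries a household's own yes/no affordability
rating alongside them as a subjective indicator, cross-classifies the two,
and models the socioeconomic factors associated with each type of
objective/subjective disagreement. Because the household expenditure
microdata such analyses run on are usually access-restricted, the package
ships a synthetic household-survey generator that reproduces the structure of
a multi-wave expenditure survey (itemized spending, income, composition,
socioeconomic covariates, provincial clustering), so the full pipeline is
runnable and testable end to end.

## The indicators

For a household with out-of-pocket (OOP) health spending $O$, total annual
expenditure $T$ (the sum of its itemized spending, including $O$), food
spending $F$, and size $s$ with equivalent size $s^{0.56}$:

| Method | CHE when | Essential-spending allowance |
|---|---|---|
| budget share | $O/T > 25\%$ | none |
| actual food spending | $O/(T-F) > 40\%$ | the household's own food spending |
| partial normative food | $O/(T - \mathrm{SF}\cdot s^{0.56}) > 40\%$ | $\mathrm{SF}$ = mean per-equivalent food spending of households whose food share lies in the 45th–55th percentile window of their wave (households with $T < \mathrm{SF}\cdot s^{0.56}$ fall back to actual food) |
| normative subsistence | $O/\mathrm{CTP} > 40\%$ | $\mathrm{CTP} = T - \mathrm{SS}\cdot s^{0.56}$, with $\mathrm{SS}$ = mean per-equivalent subsistence spending (food + housing + utilities) of households in the 25th–35th percentile window of total expenditure |
| self-rated | the household reports its OOP health spending over the past year was too high to afford | — |

All thresholds are strict, percentile windows are closed intervals on type-7
quantiles, and a household with non-positive capacity to pay is counted as
CHE whenever it incurs any OOP at all.

Two discrepancy outcomes feed logistic models per objective method: **A**,
self-rated CHE on objective-negative households ("felt but not measured"),
and **B**, one minus the self-rating on objective-positive households
("measured but not felt"). Models report adjusted odds ratios with 95% Wald
CIs, McFadden pseudo-R² and AIC; a null random-intercept logit (adaptive
Gauss–Hermite quadrature) estimates the between-province intraclass
correlation $v/(v+\pi^2/3)$ to decide whether single-level modelling is
adequate (conventional threshold 0.059).

## Worked example

Five singleton households with totals (100, 200, 300, 400, 500), food
spending (60, 100, 120, 140, 150) — food shares (.60, .50, .40, .35, .30) —
and subsistence spending (80, 120, 150, 160, 170):

```python
import pandas as pd
from che_gap import (
    estimate_normative_food, estimate_normative_subsistence,
    partial_normative_food_flag, normative_subsistence_flag,
)

wave = pd.DataFrame({
    "household_id": range(1, 6),
    "wave": 2013,
    "residency": "urban",
    "household_size": 1,
    "exp_food":       [60.0, 100.0, 120.0, 140.0, 150.0],
    "exp_housing":    [20.0,  20.0,  30.0,  20.0,  20.0],
    "exp_utilities":  [ 0.0,   0.0,   0.0,   0.0,   0.0],
    "exp_oop_health": [ 5.0,   0.0,  80.0, 100.0,  50.0],
    "exp_other":      [15.0,  80.0,  70.0, 140.0, 280.0],
    "self_rated_unaffordable": pd.array([1, 0, 1, 0, 0], dtype="Int64"),
})

food = estimate_normative_food(wave)
subs = estimate_normative_subsistence(wave)
a = partial_normative_food_flag(oop=80, total=300, food=120, household_size=1, estimate=food)
b = normative_subsistence_flag(oop=5, total=100, household_size=1, estimate=subs)
```

Formatting the estimates and assessments prints:

```
standard food (per equivalent adult):        120.0  (window 0.39-0.42, 1 household)
standard subsistence (per equivalent adult): 120.0  (window 200-240, 1 household)
household 3, partial normative food: capacity to pay = 180, ratio = 0.444, CHE = 1
household 1, normative subsistence:  capacity to pay = -20, CHE = 1  (negative capacity to pay, any OOP counts)
```

The 45th–55th percentile window of the food shares is [0.39, 0.42], so only
the share-0.40 household defines the food standard (120 per equivalent
adult). Household 3's capacity to pay under that standard is 300 − 120 = 180
and its OOP ratio 80/180 ≈ 0.444 exceeds 40%: CHE. Household 1's capacity to
pay under the subsistence standard is 100 − 120 = −20; with any OOP at all it
is counted as CHE.

## Command line

The `che-gap` command chains the stages, or runs them separately:

```sh
che-gap run --seed 11 --out demo_run --models A:budget_share
che-gap simulate --seed 3 --out records.csv
che-gap prepare --in records.csv --out prepared.csv --log exclusions.json
che-gap indicators --in prepared.csv --out assessments.csv --estimates estimates.json
che-gap discrepancy --assessments assessments.csv --out discrepancy.csv
che-gap regress --in prepared.csv --assessments assessments.csv --models all --out models.json
```

`run` writes every artifact (records, exclusion log, x-tile cutoffs,
per-wave normative estimates, incidence overall and by urban/rural residency,
2×2 discrepancy tables, model results, ICC diagnostics, manifest) as
CSV/JSON and prints the incidence table, e.g. for the budget-share rows:

```
      method  wave    n  n_flagged  incidence_pct
budget_share  2013 6708        835          12.45
budget_share  2017 6710        853          12.71
budget_share  2019 6649        842          12.66
budget_share  2021 6585        797          12.10
  self_rated  2013 6708       1841          27.44
```

Incidence denominators are households with positive OOP spending by default
(those that sought care); `incidence_denominator: all` switches to all
retained households.

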