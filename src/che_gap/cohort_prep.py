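"""Cohort construction: exclusion rules, x-tile covariates, per-model deletion.

Two exclusion rules define the analysis cohort, applied in order with exact
accounting: (1) respondents outside the survey's eligible 18-69 age range are
dropped; (2) households that rated their out-of-pocket (OOP) health spending
unaffordable while reporting zero OOP spending are dropped, since the
subjective and objective indicators cannot be compared for them.

Continuous covariates (household size, gender ratio, per-capita income,
proportion of non-working-age members, provincial per-capita health budget)
are cut into within-wave quantile groups ("x-tiles"): tertiles for all but
income, which uses quintiles.  Quantiles use linear interpolation between
order statistics (NumPy's default, the classical type-7 convention), and a
value v falls in group i when cutpoint[i-1] < v <= cutpoint[i] — ties at a
cutpoint go to the lower group.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from che_gap.errors import (
    DegenerateCutoffError,
    ModelInfeasibleError,
    SchemaError,
)
from che_gap.synthetic_data import (
    CLASS_LEVELS,
    EDUCATION_LEVELS,
    INSURANCE_LEVELS,
    REGION_LEVELS,
    RESIDENCY_LEVELS,
)

AGE_MIN, AGE_MAX = 18, 69


@dataclass
class ExclusionLog:
    """Full accounting of the two-rule exclusion cascade."""

    initial_total: int
    per_wave_initial: dict
    excluded_age: int
    excluded_unaffordable_zero_oop: int
    final_total: int
    per_wave_final: dict

    def __post_init__(self):
        if (
            self.final_total
            != self.initial_total - self.excluded_age - self.excluded_unaffordable_zero_oop
        ):
            raise ValueError("exclusion log does not reconcile")
        if min(
            self.initial_total,
            self.excluded_age,
            self.excluded_unaffordable_zero_oop,
            self.final_total,
        ) < 0:
            raise ValueError("exclusion log counts must be non-negative")

    @property
    def excluded_age_pct(self) -> float:
        """Percentage of the initial sample dropped by the age rule."""
        return 100.0 * self.excluded_age / self.initial_total if self.initial_total else 0.0

    @property
    def excluded_unaffordable_zero_oop_pct(self) -> float:
        """Percentage dropped by the unaffordable-with-zero-OOP rule."""
        return (
            100.0 * self.excluded_unaffordable_zero_oop / self.initial_total
            if self.initial_total
            else 0.0
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_age_pct"] = round(self.excluded_age_pct, 2)
        d["excluded_unaffordable_zero_oop_pct"] = round(
            self.excluded_unaffordable_zero_oop_pct, 2
        )
        return d


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the two exclusion rules; return retained records and the log.

    Records with a missing age, self-rating or OOP value pass through this
    gate (they are handled later by per-model deletion).  Rule application is
    total: no input raises.
    """
    per_wave_initial = records["wave"].value_counts().sort_index()
    age = records["respondent_age"]
    age_bad = age.notna() & ((age < AGE_MIN) | (age > AGE_MAX))
    after_age = records.loc[~age_bad]

    self_rated = after_age["self_rated_unaffordable"]
    oop = after_age["exp_oop_health"]
    zero_oop_bad = self_rated.notna() & oop.notna() & (self_rated == 1) & (oop == 0)
    retained = after_age.loc[~zero_oop_bad]

    log = ExclusionLog(
        initial_total=int(len(records)),
        per_wave_initial={int(k): int(v) for k, v in per_wave_initial.items()},
        excluded_age=int(age_bad.sum()),
        excluded_unaffordable_zero_oop=int(zero_oop_bad.sum()),
        final_total=int(len(retained)),
        per_wave_final={
            int(k): int(v)
            for k, v in retained["wave"].value_counts().sort_index().items()
        },
    )
    return retained.reset_index(drop=True), log


@dataclass(frozen=True)
class XtileCutoffs:
    """Within-wave quantile cutpoints for one covariate."""

    variable: str
    wave: int
    k: int
    cutpoints: tuple

    def __post_init__(self):
        cps = self.cutpoints
        if len(cps) != self.k - 1 or any(a >= b for a, b in zip(cps, cps[1:])):
            raise DegenerateCutoffError(self.variable, self.wave, self.k, len(set(cps)))


def compute_xtile_cutoffs(values, k: int, wave: int, variable: str = "") -> XtileCutoffs:
    """Empirical quantile cutpoints at i/k (type-7, linear interpolation)."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    n_distinct = len(np.unique(arr))
    if n_distinct < k:
        raise DegenerateCutoffError(variable, wave, k, n_distinct)
    cps = np.quantile(arr, [i / k for i in range(1, k)], method="linear")
    if np.any(np.diff(cps) <= 0):
        raise DegenerateCutoffError(variable, wave, k, n_distinct)
    cuts = XtileCutoffs(variable=variable, wave=wave, k=k, cutpoints=tuple(float(c) for c in cps))
    groups = assign_xtile(arr, cuts)
    if len(np.unique(groups)) < k:
        raise DegenerateCutoffError(variable, wave, k, n_distinct)
    return cuts


def assign_xtile(values, cutoffs: XtileCutoffs):
    """Group index in 0..k-1 per value: cutpoint[i-1] < v <= cutpoint[i].

    Missing values map to missing group labels.  Idempotent at boundaries: a
    value equal to a cutpoint always lands in the lower group.
    """
    ser = pd.Series(values, dtype="float64")
    idx = np.searchsorted(np.asarray(cutoffs.cutpoints), ser.to_numpy(), side="left")
    out = pd.Series(idx, index=ser.index, dtype="Int64")
    out[ser.isna()] = pd.NA
    return out


# Covariate schema: tertiles unless stated; labels are ordered low -> high,
# reference levels are those used by the association models.
XTILE_SPECS = {
    "household_size_cat": ("household_size", 3, ("small", "middle", "large")),
    "gender_ratio_cat": ("gender_ratio", 3, ("lower", "middle", "higher")),
    "income_quintile": (
        "income_per_capita",
        5,
        ("lowest", "low", "middle", "high", "highest"),
    ),
    "prop_nonworking_cat": ("prop_nonworking_age", 3, ("lower", "middle", "higher")),
    "health_budget_cat": ("province_health_budget_pc", 3, ("lower", "middle", "higher")),
}

PASSTHROUGH_LEVELS = {
    "education_highest": EDUCATION_LEVELS,
    "perceived_class": CLASS_LEVELS,
    "insurance": INSURANCE_LEVELS,
    "residency": RESIDENCY_LEVELS,
    "region": REGION_LEVELS,
}

REFERENCE_LEVELS = {
    "household_size_cat": "small",
    "gender_ratio_cat": "lower",
    "aged_care_need": 0,
    "childcare_need": 0,
    "education_highest": "tertiary",
    "income_quintile": "highest",
    "perceived_class": "upper",
    "prop_nonworking_cat": "lower",
    "unemployment_any": 0,
    "residency": "urban",
    "hukou_not_aligned": 0,
    "insurance": "none",
    "health_budget_cat": "lower",
    "region": "eastern",
}

#: Continuous originals used by the continuous-form robustness models, paired
#: with the categorical column they replace.
CONTINUOUS_SUBSTITUTES = {
    "household_size_cat": "household_size",
    "gender_ratio_cat": "gender_ratio",
    "income_quintile": "income_per_capita",
    "prop_nonworking_cat": "prop_nonworking_age",
    "health_budget_cat": "province_health_budget_pc",
}


def build_covariates(
    records: pd.DataFrame,
    cutoffs: Mapping[tuple[str, int], XtileCutoffs] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Attach the categorized covariates used by the association models.

    X-tile cutoffs are computed per wave from ``records`` unless supplied.
    Expenditure and identifier fields are passed through untouched; the
    continuous originals are kept alongside their categorical versions for
    the continuous-form robustness models.  Returns ``(table, cutoffs)``.
    """
    out = records.copy()
    out["gender_ratio"] = out["n_female"].astype(float) / out["household_size"].astype(float)
    out["aged_care_need"] = out["has_member_65plus"]
    out["childcare_need"] = out["has_member_under5"]
    out["hukou_not_aligned"] = (1 - out["hukou_aligned"]).astype("Int64")

    for col, levels in PASSTHROUGH_LEVELS.items():
        vals = out[col].dropna()
        unknown = set(vals) - set(levels)
        if unknown:
            bad = out.index[out[col].isin(unknown)][0]
            raise SchemaError(
                f"unknown level(s) {sorted(unknown)} in field {col!r} (first at row {bad})"
            )

    computed: dict[tuple[str, int], XtileCutoffs] = dict(cutoffs or {})
    for new_col, (src, k, labels) in XTILE_SPECS.items():
        pieces = []
        for wave, grp in out.groupby("wave", sort=True):
            key = (src, int(wave))
            if key not in computed:
                computed[key] = compute_xtile_cutoffs(grp[src], k, int(wave), variable=src)
            idx = assign_xtile(grp[src], computed[key])
            lab = idx.map(lambda i: labels[int(i)] if pd.notna(i) else pd.NA)
            pieces.append(pd.Series(lab, index=grp.index))
        out[new_col] = pd.concat(pieces).sort_index()
    return out, computed


def per_model_deletion(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Listwise deletion for one model: drop rows incomplete on its columns.

    Each model drops only its own incomplete rows (the outcome plus the
    model's covariates), so the retained n varies across models.  Returns the
    analysis table and a report with dropped count and percentage.
    """
    cols = [outcome, *covariates]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"analysis table lacks column(s): {missing_cols}")
    complete = table[cols].notna().all(axis=1)
    kept = table.loc[complete]
    n_in, n_kept = len(table), len(kept)
    report = {
        "outcome": outcome,
        "n_input": n_in,
        "n_used": n_kept,
        "n_dropped": n_in - n_kept,
        "pct_dropped": round(100.0 * (n_in - n_kept) / n_in, 2) if n_in else 0.0,
    }
    if n_kept == 0:
        raise ModelInfeasibleError(f"no complete rows for outcome {outcome!r}")
    return kept, report
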