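"""Synthetic household expenditure survey generator.

Produces repeated cross-sectional household records with the structure needed
by the downstream stages: itemized annual expenditures (food, housing,
utilities, out-of-pocket health, other), per-capita income, household
composition summaries, socioeconomic covariates, a provincial identifier with
region and per-capita provincial health budget, and a binary self-rating of
whether the household's out-of-pocket (OOP) health spending over the past
year was too high to be affordable.

The generating mechanisms, in outline:

* income per capita is log-normal within three socioeconomic strata;
* the food share of non-health spending declines with log income (an Engel
  curve), so food-share-based normative standards behave as they do in real
  budget surveys;
* OOP health spending is a three-part mixture — zero, a moderate log-normal
  ratio of non-health spending, and a heavy ratio component that produces the
  catastrophic tail (including households whose capacity to pay under a
  subsistence standard is negative);
* the subjective rating comes from a latent propensity combining the OOP
  burden ratio, a low-socioeconomic-status index, and care needs, plus
  logistic noise — so at equal objective burden, poorer households are more
  likely to self-rate their health spending unaffordable, by construction.

All randomness flows from ``SimConfig.seed`` (or an explicit ``seed``
argument); a fixed seed yields a byte-identical table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from che_gap.config import MISSABLE_FIELDS, PerceptionParams, SimConfig
from che_gap.errors import ConfigurationError, SchemaError

EDUCATION_LEVELS = ("primary", "middle_school", "vocational", "tertiary")
CLASS_LEVELS = ("upper", "middle", "lower")
INSURANCE_LEVELS = ("none", "UEBMI", "URBMI", "GMI", "NRCMS", "other")
RESIDENCY_LEVELS = ("urban", "rural")
REGION_LEVELS = ("eastern", "central", "western")

EXPENDITURE_COLUMNS = ("exp_food", "exp_housing", "exp_utilities", "exp_oop_health", "exp_other")

#: Canonical column order of the household-record schema.
COLUMNS = (
    "household_id",
    "wave",
    "province_id",
    "household_size",
    "n_female",
    "has_member_65plus",
    "has_member_under5",
    "prop_nonworking_age",
    "exp_food",
    "exp_housing",
    "exp_utilities",
    "exp_oop_health",
    "exp_other",
    "income_per_capita",
    "self_rated_unaffordable",
    "respondent_age",
    "education_highest",
    "perceived_class",
    "unemployment_any",
    "residency",
    "hukou_aligned",
    "insurance",
    "region",
    "province_health_budget_pc",
)

_INT_COLUMNS = (
    "household_id",
    "wave",
    "province_id",
    "household_size",
    "n_female",
    "has_member_65plus",
    "has_member_under5",
    "self_rated_unaffordable",
    "respondent_age",
    "unemployment_any",
    "hukou_aligned",
)


def _region_of_province(province_id: np.ndarray, n_provinces: int) -> np.ndarray:
    """Partition province ids into eastern/central/western blocks (11/8/12 of 31)."""
    n_east = max(1, round(n_provinces * 11 / 31))
    n_central = max(1, round(n_provinces * 8 / 31))
    region = np.full(province_id.shape, "western", dtype=object)
    region[province_id <= n_east] = "eastern"
    mask = (province_id > n_east) & (province_id <= n_east + n_central)
    region[mask] = "central"
    return region


def total_expenditure(records: pd.DataFrame) -> pd.Series:
    """Total household expenditure: the sum of the itemized expenditures."""
    return sum(records[c].astype(float) for c in EXPENDITURE_COLUMNS)


def low_ses_index(records: pd.DataFrame) -> pd.Series:
    """Low-socioeconomic-status index in [0, 1], from observable covariates.

    Combines the household's within-wave income rank (inverted), low perceived
    social class, low educational attainment and unemployment.  This is the
    index the latent self-rating model weighs with its SES coefficient.
    """
    income_pctile = (
        records.groupby("wave")["income_per_capita"].rank(pct=True).astype(float)
    )
    low_class = (records["perceived_class"] == "lower").astype(float)
    low_edu = records["education_highest"].isin(("primary", "middle_school")).astype(float)
    unemployed = records["unemployment_any"].fillna(0).astype(float)
    return (
        0.35 * (1.0 - income_pctile)
        + 0.25 * low_class
        + 0.25 * low_edu
        + 0.15 * unemployed
    )


def oop_burden_ratio(records: pd.DataFrame) -> pd.Series:
    """OOP health spending over non-food spending, capped at 2 (burden proxy)."""
    total = total_expenditure(records)
    nonfood = (total - records["exp_food"].astype(float)).clip(lower=1e-9)
    return (records["exp_oop_health"].astype(float) / nonfood).clip(upper=2.0)


def generate_self_rating(
    records: pd.DataFrame,
    perception_params: PerceptionParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill ``self_rated_unaffordable`` from the latent perception model.

    The latent propensity is ``a * burden + b * low_ses + c * care_need -
    cutoff + noise`` with logistic noise; the self-rating is 1 when the
    propensity is positive.  With ``noise_scale = 0`` the rating is a
    deterministic threshold.  Returns a copy of ``records``.
    """
    params = perception_params or PerceptionParams()
    params.validate()
    out = records.copy()
    burden = oop_burden_ratio(out).to_numpy(dtype=float)
    ses = low_ses_index(out).to_numpy(dtype=float)
    care = (
        out["has_member_65plus"].astype(float) + out["has_member_under5"].astype(float)
    ).to_numpy()
    latent = (
        params.burden_weight * burden
        + params.ses_weight * ses
        + params.care_weight * care
        - params.cutoff
    )
    if "province_intercept" in out.columns:
        latent = latent + out["province_intercept"].to_numpy(dtype=float)
    rng = np.random.default_rng([seed, 101])
    if params.noise_scale > 0:
        latent = latent + rng.logistic(0.0, params.noise_scale, size=len(out))
    out["self_rated_unaffordable"] = (latent > 0).astype("int64")
    return out


def _inject_missingness(df: pd.DataFrame, rates, rng: np.random.Generator) -> pd.DataFrame:
    for field, rate in rates.items():
        if rate <= 0:
            continue
        if field not in MISSABLE_FIELDS:
            raise ConfigurationError(f"missingness_rates: unknown field {field!r}")
        mask = rng.random(len(df)) < rate
        df.loc[mask, field] = pd.NA
    return df


def generate_population(config: SimConfig | None = None) -> pd.DataFrame:
    """Generate the full multi-wave household table.

    Deterministic given ``config.seed``.  Returns a DataFrame with the
    canonical column order; integer-coded fields use pandas nullable ``Int64``
    so that injected missing values survive a CSV round trip as empty fields.
    """
    config = config or SimConfig()
    config.validate()

    # Province-level attributes are drawn once so they are shared across waves.
    prov_rng = np.random.default_rng([config.seed, 17])
    prov_ids = np.arange(1, config.n_provinces + 1)
    prov_region = _region_of_province(prov_ids, config.n_provinces)
    region_budget_mu = {"eastern": 6.3, "central": 6.0, "western": 6.1}
    prov_budget_base = np.exp(
        np.array([region_budget_mu[r] for r in prov_region])
        + prov_rng.normal(0.0, 0.18, size=config.n_provinces)
    )
    prov_intercept = (
        prov_rng.normal(0.0, config.province_intercept_sd, size=config.n_provinces)
        if config.province_intercept_sd > 0
        else np.zeros(config.n_provinces)
    )

    strata = list(config.income_lognormal_params)
    frames = []
    for wave_idx, wave in enumerate(config.waves):
        rng = np.random.default_rng([config.seed, 1000 + wave_idx])
        n = config.n_households_per_wave

        province = rng.integers(1, config.n_provinces + 1, size=n)
        region = _region_of_province(province, config.n_provinces)
        # Provincial per-capita health budget grows ~6%/yr from the first wave.
        growth = 1.06 ** (wave - config.waves[0])
        budget_pc = prov_budget_base[province - 1] * growth

        stratum_idx = rng.choice(len(strata), size=n, p=list(config.ses_stratum_probs))
        mus = np.array([config.income_lognormal_params[s][0] for s in strata])
        sigmas = np.array([config.income_lognormal_params[s][1] for s in strata])
        income_pc = np.exp(rng.normal(mus[stratum_idx], sigmas[stratum_idx]))

        size = 1 + rng.poisson(1.8, size=n)
        size = np.clip(size, 1, 9)
        n_female = rng.binomial(size, 0.49)
        is_low = stratum_idx == 0
        is_high = stratum_idx == len(strata) - 1
        has65 = (rng.random(n) < (0.27 + 0.07 * is_low)).astype(int)
        has5 = (rng.random(n) < 0.26).astype(int)
        prop_nonwork = np.clip(
            rng.beta(1.5, 4.0, size=n) + 0.18 * has65 + 0.10 * has5, 0.0, 1.0
        )

        # Household budget: non-health spending is a consumption share of
        # household income; items split by Engel-curve food share, then
        # housing/utilities shares of the non-food remainder.
        hh_income = income_pc * size
        cons_rate = 0.60 + 0.30 * rng.beta(2.0, 2.0, size=n)
        nonhealth = hh_income * cons_rate
        ec = config.engel_curve_params
        food_share = np.clip(
            ec["base_share"]
            - ec["slope"] * (np.log(income_pc) - ec["log_income_anchor"])
            + rng.normal(0.0, ec["noise_sd"], size=n),
            ec["min_share"],
            ec["max_share"],
        )
        exp_food = nonhealth * food_share
        remainder = nonhealth - exp_food
        housing_share = np.clip(rng.normal(0.15, 0.05, size=n), 0.04, 0.45)
        exp_housing = remainder * housing_share
        util_share = np.clip(rng.normal(0.10, 0.03, size=n), 0.02, 0.30)
        exp_utilities = (remainder - exp_housing) * util_share
        exp_other = remainder - exp_housing - exp_utilities

        # OOP health spending: zero / moderate / heavy ratio mixture.
        op = config.oop_shock_params
        comp = rng.choice(
            3, size=n, p=[op["zero_weight"], op["moderate_weight"], op["heavy_weight"]]
        )
        log_mu = np.where(
            comp == 2, op["heavy_log_ratio_mu"], op["moderate_log_ratio_mu"]
        )
        log_sigma = np.where(
            comp == 2, op["heavy_log_ratio_sigma"], op["moderate_log_ratio_sigma"]
        )
        ratio = np.exp(rng.normal(log_mu, log_sigma))
        exp_oop = np.where(comp == 0, 0.0, ratio * nonhealth)

        age = rng.integers(18, 70, size=n)
        out_of_range = rng.random(n) < config.age_out_of_range_rate
        age = np.where(
            out_of_range, rng.choice([16, 17, 70, 71, 72, 75], size=n), age
        )

        edu_probs = np.select(
            [is_low, is_high],
            [
                np.full((n, 4), [0.14, 0.56, 0.20, 0.10]).T,
                np.full((n, 4), [0.01, 0.22, 0.27, 0.50]).T,
            ],
            np.full((n, 4), [0.05, 0.45, 0.27, 0.23]).T,
        ).T
        edu_idx = (rng.random(n)[:, None] > np.cumsum(edu_probs, axis=1)).sum(axis=1)
        education = np.array(EDUCATION_LEVELS, dtype=object)[edu_idx]

        class_probs = np.select(
            [is_low, is_high],
            [
                np.full((n, 3), [0.002, 0.560, 0.438]).T,
                np.full((n, 3), [0.020, 0.850, 0.130]).T,
            ],
            np.full((n, 3), [0.005, 0.780, 0.215]).T,
        ).T
        class_idx = (rng.random(n)[:, None] > np.cumsum(class_probs, axis=1)).sum(axis=1)
        perceived = np.array(CLASS_LEVELS, dtype=object)[class_idx]

        unemployment = (rng.random(n) < (0.38 + 0.18 * is_low - 0.12 * is_high)).astype(int)
        p_rural = 0.48 + 0.14 * is_low - 0.20 * is_high
        rural = rng.random(n) < p_rural
        residency = np.where(rural, "rural", "urban")
        hukou = (rng.random(n) < 0.88).astype(int)

        ins_rural = [0.12, 0.02, 0.04, 0.01, 0.77, 0.04]
        ins_urban = [0.18, 0.38, 0.26, 0.03, 0.08, 0.07]
        ins_probs = np.where(rural[:, None], ins_rural, ins_urban)
        ins_idx = (rng.random(n)[:, None] > np.cumsum(ins_probs, axis=1)).sum(axis=1)
        insurance = np.array(INSURANCE_LEVELS, dtype=object)[np.clip(ins_idx, 0, 5)]

        df = pd.DataFrame(
            {
                "household_id": wave * 100_000 + np.arange(1, n + 1),
                "wave": wave,
                "province_id": province,
                "household_size": size,
                "n_female": n_female,
                "has_member_65plus": has65,
                "has_member_under5": has5,
                "prop_nonworking_age": np.round(prop_nonwork, 6),
                "exp_food": np.round(exp_food, 2),
                "exp_housing": np.round(exp_housing, 2),
                "exp_utilities": np.round(exp_utilities, 2),
                "exp_oop_health": np.round(exp_oop, 2),
                "exp_other": np.round(exp_other, 2),
                "income_per_capita": np.round(income_pc, 2),
                "respondent_age": age,
                "education_highest": education,
                "perceived_class": perceived,
                "unemployment_any": unemployment,
                "residency": residency,
                "hukou_aligned": hukou,
                "insurance": insurance,
                "region": region,
                "province_health_budget_pc": np.round(budget_pc, 2),
                "province_intercept": prov_intercept[province - 1],
            }
        )
        frames.append(df)

    records = pd.concat(frames, ignore_index=True)
    records = generate_self_rating(records, config.perception_params, seed=config.seed)
    records = records.drop(columns=["province_intercept"])

    miss_rng = np.random.default_rng([config.seed, 55])
    for col in _INT_COLUMNS:
        records[col] = records[col].astype("Int64")
    records = _inject_missingness(records, config.missingness_rates, miss_rng)
    return records[list(COLUMNS)]


def write_records(records: pd.DataFrame, path) -> None:
    """Write household records as UTF-8 CSV; missing values are empty fields."""
    records.to_csv(path, index=False, encoding="utf-8", na_rep="")


def read_records(path) -> pd.DataFrame:
    """Read a household-record CSV written by :func:`write_records`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("wave", "province_id", "household_size") if c not in df.columns]
    if missing:
        raise SchemaError(f"input is missing required column(s): {missing}")
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df
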