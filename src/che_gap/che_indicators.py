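"""Objective and subjective catastrophic health expenditure (CHE) indicators.

Five indicators are computed per household:

* **budget_share** — OOP health spending / total household expenditure,
  CHE when the share strictly exceeds 25%;
* **actual_food** — OOP / (total - actual food spending), CHE above 40%;
* **partial_normative_food** — OOP / (total - standard food spending), where
  the standard is the average per-equivalent-adult food spending of
  households whose food share lies in the 45th-55th percentile window of
  their wave; households whose total falls below their standard fall back to
  actual food spending.  CHE above 40%;
* **normative_subsistence** — OOP / capacity to pay, where capacity to pay is
  total minus a standard subsistence allowance (food + housing + utilities)
  averaged per equivalent adult over households in the 25th-35th percentile
  window of total expenditure.  CHE above 40%; households with non-positive
  capacity to pay are counted as CHE whenever they incur any OOP at all;
* **self_rated** — the household's own yes/no report that its OOP health
  spending over the past year was too high to afford, carried unchanged.

Household totals are converted to per-equivalent-adult amounts with the
equivalence scale (household size)^0.56.  All thresholds are strict: a ratio
exactly at the threshold is not CHE.  Percentile windows are inclusive of
both bounds and use type-7 (linear-interpolation) quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from che_gap.config import IndicatorConfig
from che_gap.errors import EstimationError, PipelineOrderError, ValidationError
from che_gap.synthetic_data import total_expenditure

logger = logging.getLogger(__name__)

OBJECTIVE_METHODS = (
    "budget_share",
    "actual_food",
    "partial_normative_food",
    "normative_subsistence",
)
ALL_METHODS = OBJECTIVE_METHODS + ("self_rated",)

SUBSISTENCE_ITEMS = ("exp_food", "exp_housing", "exp_utilities")


@dataclass(frozen=True)
class NormativeEstimate:
    """Per-wave standard food or subsistence spending per equivalent adult."""

    wave: int
    kind: str  # "food" | "subsistence"
    per_equivalent_standard: float
    n_window_households: int
    window_bounds: tuple[float, float]

    def __post_init__(self):
        if self.per_equivalent_standard < 0:
            raise EstimationError("per_equivalent_standard must be >= 0")
        if self.n_window_households < 1:
            raise EstimationError("normative window selected no households")


@dataclass(frozen=True)
class CheAssessment:
    """One household's assessment under one method."""

    household_key: object
    method: str
    numerator: float | None
    denominator: float | None
    ratio: float | None
    che_flag: int | None


def _window_select(values: pd.Series, lo: float, hi: float) -> pd.Series:
    """Boolean mask of values inside the closed window [lo, hi].

    In very small waves both interpolated percentile bounds can fall strictly
    between the same pair of adjacent order statistics, leaving the closed
    window empty; the household(s) closest to the window midpoint are then
    selected instead, so the estimator is total for any wave with data.
    """
    selected = (values >= lo) & (values <= hi)
    if not selected.any():
        dist = (values - (lo + hi) / 2.0).abs()
        selected = dist == dist.min()
    return selected


def equivalent_size(household_size: int, exponent: float = 0.56) -> float:
    """Equivalent household size: size raised to the equivalence exponent."""
    if household_size < 1:
        raise ValidationError(f"household_size must be >= 1, got {household_size}")
    return float(household_size) ** exponent


def _threshold_flag(oop: float, denominator: float, threshold: float) -> CheAssessment:
    """Strict-threshold rule with the degenerate capacity-to-pay convention.

    A non-positive denominator is the limit of an unbounded ratio: any OOP at
    all is catastrophic, no OOP is not.
    """
    if denominator > 0:
        ratio = oop / denominator
        return CheAssessment(None, "", oop, denominator, ratio, int(ratio > threshold))
    return CheAssessment(None, "", oop, denominator, None, int(oop > 0))


def _check_oop(oop: float, total: float) -> None:
    if oop < 0:
        raise ValidationError(f"OOP spending must be >= 0, got {oop}")
    if oop > total:
        raise ValidationError(f"OOP spending {oop} exceeds total expenditure {total}")


def budget_share_flag(
    oop: float, total: float, config: IndicatorConfig | None = None
) -> CheAssessment:
    """Budget-share indicator: OOP / total expenditure, CHE strictly above 25%."""
    config = config or IndicatorConfig()
    if total <= 0:
        return CheAssessment(None, "budget_share", oop, total, None, None)
    _check_oop(oop, total)
    ratio = oop / total
    return CheAssessment(
        None, "budget_share", oop, total, ratio,
        int(ratio > config.budget_share_threshold),
    )


def actual_food_flag(
    oop: float, total: float, food: float, config: IndicatorConfig | None = None
) -> CheAssessment:
    """Actual-food indicator: OOP / (total - actual food), CHE strictly above 40%."""
    config = config or IndicatorConfig()
    _check_oop(oop, total)
    if not (0 <= food <= total):
        raise ValidationError(f"food spending {food} outside [0, total={total}]")
    a = _threshold_flag(oop, total - food, config.ctp_threshold)
    return CheAssessment(None, "actual_food", a.numerator, a.denominator, a.ratio, a.che_flag)


def estimate_normative_food(
    wave_records: pd.DataFrame, config: IndicatorConfig | None = None, wave: int | None = None
) -> NormativeEstimate:
    """Standard food spending for one wave.

    The standard is the mean per-equivalent-adult food spending of households
    whose food share (food / total) lies within the configured percentile
    window of the wave's food-share distribution, bounds inclusive.
    """
    config = config or IndicatorConfig()
    total = total_expenditure(wave_records).astype(float)
    ok = total > 0
    if int(ok.sum()) < 2:
        raise EstimationError("need at least 2 households with positive total expenditure")
    sub = wave_records.loc[ok]
    total = total.loc[ok]
    shares = sub["exp_food"].astype(float) / total
    lo, hi = np.percentile(shares.to_numpy(), list(config.food_share_window), method="linear")
    selected = _window_select(shares, lo, hi)
    eq = sub["household_size"].astype(float) ** config.equivalence_exponent
    per_eq = (sub["exp_food"].astype(float) / eq)[selected]
    return NormativeEstimate(
        wave=int(wave if wave is not None else sub["wave"].iloc[0]),
        kind="food",
        per_equivalent_standard=float(per_eq.mean()),
        n_window_households=int(selected.sum()),
        window_bounds=(float(lo), float(hi)),
    )


def estimate_normative_subsistence(
    wave_records: pd.DataFrame, config: IndicatorConfig | None = None, wave: int | None = None
) -> NormativeEstimate:
    """Standard subsistence spending (food + housing + utilities) for one wave.

    Households are ranked by total expenditure — per equivalent adult by
    default (``subsistence_ranking="per_equivalent"``), or raw — and those in
    the configured percentile window (bounds inclusive) contribute their
    per-equivalent subsistence spending to the mean standard.
    """
    config = config or IndicatorConfig()
    total = total_expenditure(wave_records).astype(float)
    ok = total > 0
    if int(ok.sum()) < 2:
        raise EstimationError("need at least 2 households with positive total expenditure")
    sub = wave_records.loc[ok]
    total = total.loc[ok]
    eq = sub["household_size"].astype(float) ** config.equivalence_exponent
    ranking = total / eq if config.subsistence_ranking == "per_equivalent" else total
    lo, hi = np.percentile(ranking.to_numpy(), list(config.subsistence_window), method="linear")
    selected = _window_select(ranking, lo, hi)
    subsistence = sum(sub[c].astype(float) for c in SUBSISTENCE_ITEMS)
    per_eq = (subsistence / eq)[selected]
    return NormativeEstimate(
        wave=int(wave if wave is not None else sub["wave"].iloc[0]),
        kind="subsistence",
        per_equivalent_standard=float(per_eq.mean()),
        n_window_households=int(selected.sum()),
        window_bounds=(float(lo), float(hi)),
    )


def partial_normative_food_flag(
    oop: float,
    total: float,
    food: float,
    household_size: int,
    estimate: NormativeEstimate | None,
    config: IndicatorConfig | None = None,
) -> CheAssessment:
    """Partial-normative-food indicator for one household.

    Capacity to pay is total minus the household's standard food spending
    (per-equivalent standard x equivalent size); households whose total is
    strictly below their standard fall back to total minus actual food.
    """
    config = config or IndicatorConfig()
    if estimate is None or estimate.kind != "food":
        raise PipelineOrderError("partial_normative_food requires the wave's food estimate")
    _check_oop(oop, total)
    standard = estimate.per_equivalent_standard * equivalent_size(
        household_size, config.equivalence_exponent
    )
    denominator = (total - food) if total < standard else (total - standard)
    a = _threshold_flag(oop, denominator, config.ctp_threshold)
    return CheAssessment(
        None, "partial_normative_food", a.numerator, a.denominator, a.ratio, a.che_flag
    )


def normative_subsistence_flag(
    oop: float,
    total: float,
    household_size: int,
    estimate: NormativeEstimate | None,
    config: IndicatorConfig | None = None,
) -> CheAssessment:
    """Normative-subsistence indicator for one household.

    Capacity to pay is total minus the household's standard subsistence
    spending.  Very poor households with non-positive capacity to pay are
    counted as CHE whenever they incur any OOP at all.
    """
    config = config or IndicatorConfig()
    if estimate is None or estimate.kind != "subsistence":
        raise PipelineOrderError(
            "normative_subsistence requires the wave's subsistence estimate"
        )
    _check_oop(oop, total)
    ctp = total - estimate.per_equivalent_standard * equivalent_size(
        household_size, config.equivalence_exponent
    )
    a = _threshold_flag(oop, ctp, config.ctp_threshold)
    return CheAssessment(
        None, "normative_subsistence", a.numerator, a.denominator, a.ratio, a.che_flag
    )


def self_rated_flag(self_rated_unaffordable) -> CheAssessment:
    """Subjective indicator: the reported binary, carried unchanged."""
    if pd.isna(self_rated_unaffordable):
        return CheAssessment(None, "self_rated", None, None, None, None)
    return CheAssessment(
        None, "self_rated", None, None, None, int(self_rated_unaffordable)
    )


def estimate_all(
    records: pd.DataFrame, config: IndicatorConfig | None = None
) -> dict[tuple[int, str], NormativeEstimate]:
    """Per-wave normative food and subsistence estimates on the given sample."""
    config = config or IndicatorConfig()
    estimates: dict[tuple[int, str], NormativeEstimate] = {}
    for wave, grp in records.groupby("wave", sort=True):
        estimates[(int(wave), "food")] = estimate_normative_food(grp, config, wave=int(wave))
        estimates[(int(wave), "subsistence")] = estimate_normative_subsistence(
            grp, config, wave=int(wave)
        )
    return estimates


def assess_households(
    records: pd.DataFrame,
    config: IndicatorConfig | None = None,
    estimates: dict[tuple[int, str], NormativeEstimate] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[int, str], NormativeEstimate]]:
    """Vectorized assessment of every household under every method.

    Normative estimates are computed per wave on ``records`` (the
    post-exclusion sample) unless supplied.  Returns a long-format table with
    one row per household x method (columns: household_id, wave, residency,
    exp_oop_health, method, numerator, denominator, ratio, che_flag) and the
    estimates used.
    """
    config = config or IndicatorConfig()
    config.validate()
    if estimates is None:
        estimates = estimate_all(records, config)

    total = total_expenditure(records).to_numpy(dtype=float)
    oop = records["exp_oop_health"].astype(float).to_numpy()
    food = records["exp_food"].astype(float).to_numpy()
    size = records["household_size"].astype(float).to_numpy()
    wave = records["wave"].astype(int).to_numpy()
    eq = size**config.equivalence_exponent
    if np.any(oop < 0) or np.any(oop > total + 1e-9):
        raise ValidationError("OOP spending must lie in [0, total expenditure]")

    food_std = np.array(
        [estimates[(w, "food")].per_equivalent_standard for w in wave]
    ) * eq
    subs_std = np.array(
        [estimates[(w, "subsistence")].per_equivalent_standard for w in wave]
    ) * eq

    def _ctp_flag(denom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, oop / np.where(denom > 0, denom, 1.0), np.nan)
        flag = np.where(denom > 0, ratio > config.ctp_threshold, oop > 0).astype(float)
        return ratio, flag

    pieces = []
    base = records[["household_id", "wave", "residency"]].copy()
    base["exp_oop_health"] = oop

    # budget share
    with np.errstate(divide="ignore", invalid="ignore"):
        bs_ratio = np.where(total > 0, oop / np.where(total > 0, total, 1.0), np.nan)
    bs_flag = np.where(total > 0, (bs_ratio > config.budget_share_threshold).astype(float), np.nan)
    pieces.append(("budget_share", oop, total, bs_ratio, bs_flag))

    # actual food
    af_ratio, af_flag = _ctp_flag(total - food)
    pieces.append(("actual_food", oop, total - food, af_ratio, af_flag))

    # partial normative food
    pn_denom = np.where(total < food_std, total - food, total - food_std)
    pn_ratio, pn_flag = _ctp_flag(pn_denom)
    pieces.append(("partial_normative_food", oop, pn_denom, pn_ratio, pn_flag))

    # normative subsistence
    ns_denom = total - subs_std
    ns_ratio, ns_flag = _ctp_flag(ns_denom)
    pieces.append(("normative_subsistence", oop, ns_denom, ns_ratio, ns_flag))

    # self-rated
    sr = records["self_rated_unaffordable"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    pieces.append(("self_rated", np.full_like(oop, np.nan), np.full_like(oop, np.nan), np.full_like(oop, np.nan), sr))

    frames = []
    for method, num, den, ratio, flag in pieces:
        df = base.copy()
        df["method"] = method
        df["numerator"] = num
        df["denominator"] = den
        df["ratio"] = ratio
        df["che_flag"] = pd.array(flag, dtype="Float64").round(0).astype("Int64")
        frames.append(df)
    assessments = pd.concat(frames, ignore_index=True)
    return assessments, estimates


def compute_incidence(
    assessments: pd.DataFrame,
    by: tuple[str, ...] = ("wave",),
    denominator_rule: str = "oop_positive",
) -> pd.DataFrame:
    """CHE incidence (percent) per method and grouping keys.

    ``denominator_rule`` selects the denominator population: ``"all"`` counts
    every household with a non-missing flag; ``"oop_positive"`` (default)
    restricts to households that incurred any OOP health spending, i.e. those
    that sought care.  Empty groups are omitted with a logged warning.
    """
    if denominator_rule not in ("all", "oop_positive"):
        raise ValidationError(f"unknown denominator rule {denominator_rule!r}")
    df = assessments[assessments["che_flag"].notna()].copy()
    if denominator_rule == "oop_positive":
        df = df[df["exp_oop_health"].astype(float) > 0]
    keys = ["method", *by]
    rows = []
    for key_vals, grp in df.groupby(keys, sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty incidence group %s omitted", key_vals)
            continue
        flagged = int(grp["che_flag"].sum())
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(n=n, n_flagged=flagged, incidence_pct=round(100.0 * flagged / n, 2))
        rows.append(rec)
    return pd.DataFrame(rows)
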