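"""Configuration objects for the generator, the indicators and the pipeline.

All monetary quantities are abstract currency units per year; the analysis is
scale-free (every indicator is a ratio), so no deflation between survey waves
is applied and none is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from che_gap.errors import ConfigurationError

#: Fields that may never receive injected missing values: they are the keys
#: used for grouping and exclusion accounting.
PROTECTED_FIELDS = ("wave", "province_id", "household_size")

#: Fields eligible for missingness injection.
MISSABLE_FIELDS = (
    "income_per_capita",
    "education_highest",
    "perceived_class",
    "insurance",
    "hukou_aligned",
    "unemployment_any",
    "self_rated_unaffordable",
)


@dataclass(frozen=True)
class PerceptionParams:
    """Coefficients of the latent self-rating model.

    latent = burden_weight * (OOP burden ratio)
           + ses_weight * (low-SES index in [0, 1])
           + care_weight * (aged/child care-need indicator count)
           - cutoff + logistic noise (scale ``noise_scale``)

    and the household self-rates its health spending unaffordable when the
    latent propensity is positive.  ``ses_weight > 0`` builds in the
    mechanism by which, at equal objective burden, low-socioeconomic-status
    households are more likely to rate their spending unaffordable.
    """

    burden_weight: float = 8.5
    ses_weight: float = 1.1
    care_weight: float = 0.35
    cutoff: float = 3.1
    noise_scale: float = 1.0

    def validate(self) -> None:
        for name in ("burden_weight", "ses_weight", "care_weight", "cutoff", "noise_scale"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"perception_params.{name} must be finite, got {v!r}")
        if self.noise_scale < 0:
            raise ConfigurationError("perception_params.noise_scale must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic household-survey generator.

    Defaults emulate a four-wave repeated cross-sectional expenditure survey
    of roughly 10 000 households per wave across 31 provinces, with itemized
    annual expenditures, a three-part out-of-pocket (OOP) health-spending
    mixture (zero / moderate / heavy), an Engel-curve food share declining in
    income, and a subjective affordability rating driven by both the OOP
    burden and socioeconomic status.
    """

    n_households_per_wave: int = 10_000
    waves: Sequence[int] = (2013, 2017, 2019, 2021)
    n_provinces: int = 31
    seed: int = 0

    #: (mu, sigma) of log per-capita income for the low/middle/high SES strata.
    income_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (9.3, 0.40),
            "middle": (9.9, 0.40),
            "high": (10.5, 0.45),
        }
    )
    #: Probability of each SES stratum (same order as income_lognormal_params).
    ses_stratum_probs: tuple[float, float, float] = (0.30, 0.50, 0.20)

    #: Engel curve: food share = clip(base - slope * (log income pc - anchor),
    #: lo, hi) plus household-level noise, so the food share declines with
    #: income as in household budget data.
    engel_curve_params: Mapping[str, float] = field(
        default_factory=lambda: {
            "base_share": 0.42,
            "slope": 0.085,
            "log_income_anchor": 9.2,
            "noise_sd": 0.06,
            "min_share": 0.10,
            "max_share": 0.78,
        }
    )

    #: Three-part OOP mixture: with probability ``zero_weight`` the household
    #: spends nothing out of pocket; otherwise OOP is a log-normal multiple of
    #: non-health spending (moderate or heavy ratio component).  The heavy
    #: component produces the catastrophic tail, including households whose
    #: capacity to pay goes negative under the subsistence standard.
    oop_shock_params: Mapping[str, float] = field(
        default_factory=lambda: {
            "zero_weight": 0.33,
            "moderate_weight": 0.57,
            "heavy_weight": 0.10,
            "moderate_log_ratio_mu": math.log(0.055),
            "moderate_log_ratio_sigma": 0.90,
            "heavy_log_ratio_mu": math.log(0.50),
            "heavy_log_ratio_sigma": 0.70,
        }
    )

    perception_params: PerceptionParams = field(default_factory=PerceptionParams)

    #: Per-field probability of injected missingness (empty CSV field).
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "income_per_capita": 0.040,
            "education_highest": 0.030,
            "perceived_class": 0.020,
            "insurance": 0.020,
            "hukou_aligned": 0.010,
            "unemployment_any": 0.010,
        }
    )

    #: Standard deviation of the province random intercept on the latent
    #: self-rating scale; 0 means no provincial clustering.
    province_intercept_sd: float = 0.0

    #: Probability that a respondent's age falls outside the survey's
    #: eligible 18-69 range (keyed-in ineligible interviews).
    age_out_of_range_rate: float = 0.0008

    def validate(self) -> None:
        if self.n_households_per_wave <= 0:
            raise ConfigurationError("n_households_per_wave must be a positive integer")
        if not self.waves:
            raise ConfigurationError("waves must be non-empty")
        if self.n_provinces < 2:
            raise ConfigurationError("n_provinces must be >= 2")
        for stratum, (mu, sigma) in self.income_lognormal_params.items():
            if sigma <= 0:
                raise ConfigurationError(
                    f"income_lognormal_params[{stratum!r}]: sigma must be > 0, got {sigma}"
                )
        if abs(sum(self.ses_stratum_probs) - 1.0) > 1e-9:
            raise ConfigurationError("ses_stratum_probs must sum to 1")
        w = self.oop_shock_params
        weights = (w["zero_weight"], w["moderate_weight"], w["heavy_weight"])
        if any(x < 0 for x in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                "oop_shock_params weights must be non-negative and sum to 1"
            )
        for name, rate in self.missingness_rates.items():
            if name in PROTECTED_FIELDS:
                raise ConfigurationError(
                    f"missingness_rates may not target key field {name!r}"
                )
            if name not in MISSABLE_FIELDS:
                raise ConfigurationError(f"missingness_rates: unknown field {name!r}")
            if not (0 <= rate < 1):
                raise ConfigurationError(
                    f"missingness_rates[{name!r}] must be in [0, 1), got {rate}"
                )
        if self.province_intercept_sd < 0:
            raise ConfigurationError("province_intercept_sd must be >= 0")
        if not (0 <= self.age_out_of_range_rate < 1):
            raise ConfigurationError("age_out_of_range_rate must be in [0, 1)")
        self.perception_params.validate()


@dataclass(frozen=True)
class IndicatorConfig:
    """Thresholds, percentile windows and the equivalence exponent.

    The four objective indicators flag catastrophic health expenditure when
    the OOP share of the method's denominator *strictly* exceeds the
    threshold: 25% of total household expenditure for the budget-share
    method, 40% of capacity to pay for the three capacity-to-pay methods.
    Household totals are converted to per-equivalent-adult amounts with the
    equivalence scale (household size)^0.56.
    """

    budget_share_threshold: float = 0.25
    ctp_threshold: float = 0.40
    equivalence_exponent: float = 0.56
    food_share_window: tuple[float, float] = (45.0, 55.0)
    subsistence_window: tuple[float, float] = (25.0, 35.0)
    #: Ranking variable for the subsistence window: households are ranked by
    #: per-equivalent total expenditure ("per_equivalent", the default, for
    #: coherence with the equivalence-adjusted standard) or by raw total
    #: ("raw_total").
    subsistence_ranking: str = "per_equivalent"

    def validate(self) -> None:
        for name in ("budget_share_threshold", "ctp_threshold"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.equivalence_exponent < 0:
            raise ConfigurationError("equivalence_exponent must be >= 0")
        for name in ("food_share_window", "subsistence_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= 100):
                raise ConfigurationError(
                    f"{name} must satisfy 0 <= lower < upper <= 100, got ({lo}, {hi})"
                )
        if self.subsistence_ranking not in ("per_equivalent", "raw_total"):
            raise ConfigurationError(
                "subsistence_ranking must be 'per_equivalent' or 'raw_total', "
                f"got {self.subsistence_ranking!r}"
            )


def config_to_dict(cfg) -> dict:
    """Serialize a config dataclass to a plain dict (for manifests)."""
    d = asdict(cfg)

    def _plain(v):
        if isinstance(v, dict):
            return {k: _plain(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_plain(x) for x in v]
        return v

    return _plain(d)
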