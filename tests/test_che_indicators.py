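"""Indicator definitions: worked micro-examples, brute-force oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from che_gap.che_indicators import (
    OBJECTIVE_METHODS,
    actual_food_flag,
    assess_households,
    budget_share_flag,
    compute_incidence,
    equivalent_size,
    estimate_normative_food,
    estimate_normative_subsistence,
    normative_subsistence_flag,
    partial_normative_food_flag,
    self_rated_flag,
)
from che_gap.config import IndicatorConfig
from che_gap.errors import ValidationError
from conftest import make_wave


def five_household_wave() -> pd.DataFrame:
    """Five singleton households: the hand-enumerable worked example.

    Totals (100, 200, 300, 400, 500); food (60, 100, 120, 140, 150) so the
    food shares are (.60, .50, .40, .35, .30); subsistence spending
    (80, 120, 150, 160, 170) via housing+utilities = subsistence - food.
    """
    food = np.array([60.0, 100.0, 120.0, 140.0, 150.0])
    subsistence = np.array([80.0, 120.0, 150.0, 160.0, 170.0])
    totals = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
    oop = np.array([5.0, 0.0, 80.0, 100.0, 50.0])
    housing = subsistence - food
    other = totals - food - housing - oop
    return pd.DataFrame(
        {
            "household_id": range(1, 6),
            "wave": 2013,
            "residency": "urban",
            "household_size": 1,
            "exp_food": food,
            "exp_housing": housing,
            "exp_utilities": 0.0,
            "exp_oop_health": oop,
            "exp_other": other,
            "self_rated_unaffordable": pd.array([1, 0, 1, 0, 0], dtype="Int64"),
        }
    )


class TestEquivalentSize:
    def test_singleton_is_identity(self):
        assert equivalent_size(1) == 1.0

    def test_power_evaluation(self):
        assert equivalent_size(4, 0.56) == pytest.approx(4**0.56)
        assert equivalent_size(4, 0.56) == pytest.approx(2.17348, abs=1e-4)

    def test_linear_limit(self):
        assert equivalent_size(7, 1.0) == 7.0

    def test_zero_exponent_collapses_scale(self):
        assert all(equivalent_size(s, 0.0) == 1.0 for s in range(1, 10))

    def test_size_below_one_rejected(self):
        with pytest.raises(ValidationError):
            equivalent_size(0)


class TestBudgetShare:
    @pytest.mark.parametrize(
        "oop,total,ratio,flag",
        [
            (30, 100, 0.30, 1),
            (25, 100, 0.25, 0),  # strict at the >25% boundary
            (0, 100, 0.0, 0),
        ],
    )
    def test_threshold_is_strict(self, oop, total, ratio, flag):
        a = budget_share_flag(oop, total)
        assert a.ratio == pytest.approx(ratio)
        assert a.che_flag == flag

    def test_nonpositive_total_gives_undefined_ratio(self):
        a = budget_share_flag(0, 0)
        assert a.ratio is None and a.che_flag is None

    def test_oop_above_total_rejected(self):
        with pytest.raises(ValidationError):
            budget_share_flag(101, 100)


class TestActualFood:
    @pytest.mark.parametrize(
        "oop,total,food,flag",
        [
            (40, 140, 40, 0),  # ratio exactly 0.40: strict, not CHE
            (41, 140, 40, 1),
            (10, 60, 60, 1),  # degenerate denominator with OOP > 0
            (0, 60, 60, 0),  # degenerate denominator without OOP
        ],
    )
    def test_flags(self, oop, total, food, flag):
        assert actual_food_flag(oop, total, food).che_flag == flag


class TestNormativeEstimators:
    def test_worked_example_standard_food(self):
        est = estimate_normative_food(five_household_wave())
        assert est.window_bounds == pytest.approx((0.39, 0.42))
        assert est.n_window_households == 1
        assert est.per_equivalent_standard == pytest.approx(120.0)

    def test_worked_example_standard_subsistence(self):
        est = estimate_normative_subsistence(five_household_wave())
        assert est.window_bounds == pytest.approx((200.0, 240.0))
        assert est.per_equivalent_standard == pytest.approx(120.0)

    def test_identical_households_recover_common_value(self):
        wave = pd.DataFrame(
            {
                "wave": 2013,
                "household_size": [2] * 6,
                "exp_food": [100.0] * 6,
                "exp_housing": [50.0] * 6,
                "exp_utilities": [20.0] * 6,
                "exp_oop_health": [10.0] * 6,
                "exp_other": [40.0] * 6,
            }
        )
        eq = 2**0.56
        est_f = estimate_normative_food(wave)
        est_s = estimate_normative_subsistence(wave)
        assert est_f.per_equivalent_standard == pytest.approx(100.0 / eq)
        assert est_s.per_equivalent_standard == pytest.approx(170.0 / eq)

    @pytest.mark.parametrize("scale", [10.0, 0.01])
    def test_scale_equivariance(self, scale):
        wave = five_household_wave()
        scaled = wave.copy()
        for c in ("exp_food", "exp_housing", "exp_utilities", "exp_oop_health", "exp_other"):
            scaled[c] = scaled[c] * scale
        f0, f1 = estimate_normative_food(wave), estimate_normative_food(scaled)
        s0, s1 = estimate_normative_subsistence(wave), estimate_normative_subsistence(scaled)
        assert f1.per_equivalent_standard == pytest.approx(scale * f0.per_equivalent_standard)
        assert s1.per_equivalent_standard == pytest.approx(scale * s0.per_equivalent_standard)
        assert f1.n_window_households == f0.n_window_households


class TestPartialNormativeFood:
    def test_worked_example_fallback_branch(self):
        wave = five_household_wave()
        est = estimate_normative_food(wave)
        # household 1: total 100 < standard 120 -> denominator = 100 - 60 = 40
        a = partial_normative_food_flag(5.0, 100.0, 60.0, 1, est)
        assert a.denominator == pytest.approx(40.0)

    def test_worked_example_normative_branch(self):
        est = estimate_normative_food(five_household_wave())
        # household 3: denominator = 300 - 120 = 180; oop 80 -> ratio .444 -> CHE
        a = partial_normative_food_flag(80.0, 300.0, 120.0, 1, est)
        assert a.denominator == pytest.approx(180.0)
        assert a.ratio == pytest.approx(80 / 180)
        assert a.che_flag == 1

    def test_tie_takes_normative_branch(self):
        est = estimate_normative_food(five_household_wave())
        # total exactly equal to the standard: normative branch, denominator 0
        a = partial_normative_food_flag(1.0, 120.0, 60.0, 1, est)
        assert a.denominator == pytest.approx(0.0)
        assert a.che_flag == 1  # degenerate denominator with OOP > 0


class TestNormativeSubsistence:
    def test_negative_ctp_flags_any_oop(self):
        est = estimate_normative_subsistence(five_household_wave())
        a = normative_subsistence_flag(5.0, 100.0, 1, est)
        assert a.denominator == pytest.approx(-20.0)
        assert a.che_flag == 1

    def test_negative_ctp_without_oop_not_che(self):
        est = estimate_normative_subsistence(five_household_wave())
        assert normative_subsistence_flag(0.0, 100.0, 1, est).che_flag == 0

    def test_positive_ctp_uses_ratio(self):
        est = estimate_normative_subsistence(five_household_wave())
        a = normative_subsistence_flag(100.0, 500.0, 1, est)
        assert a.denominator == pytest.approx(380.0)
        assert a.ratio == pytest.approx(100 / 380)
        assert a.che_flag == 0


class TestSelfRated:
    def test_carried_unchanged(self):
        assert self_rated_flag(1).che_flag == 1
        assert self_rated_flag(0).che_flag == 0
        assert self_rated_flag(pd.NA).che_flag is None


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_normative_food(wave: pd.DataFrame, window=(45, 55), exponent=0.56):
    """Sort, select by explicit comparison, arithmetic mean — no vectorization."""
    rows = [
        r
        for _, r in wave.iterrows()
        if (r.exp_food + r.exp_housing + r.exp_utilities + r.exp_oop_health + r.exp_other) > 0
    ]
    shares = sorted(
        r.exp_food
        / (r.exp_food + r.exp_housing + r.exp_utilities + r.exp_oop_health + r.exp_other)
        for r in rows
    )
    lo = _type7(shares, window[0] / 100)
    hi = _type7(shares, window[1] / 100)
    def share(r):
        return r.exp_food / (
            r.exp_food + r.exp_housing + r.exp_utilities + r.exp_oop_health + r.exp_other
        )

    selected = [r for r in rows if lo <= share(r) <= hi]
    if not selected:  # empty closed window: take household(s) nearest the midpoint
        mid = (lo + hi) / 2
        best = min(abs(share(r) - mid) for r in rows)
        selected = [r for r in rows if abs(share(r) - mid) == best]
    vals = [r.exp_food / r.household_size**exponent for r in selected]
    return sum(vals) / len(vals), len(vals)


def oracle_normative_subsistence(wave: pd.DataFrame, window=(25, 35), exponent=0.56):
    rows = [
        r
        for _, r in wave.iterrows()
        if (r.exp_food + r.exp_housing + r.exp_utilities + r.exp_oop_health + r.exp_other) > 0
    ]

    def total(r):
        return r.exp_food + r.exp_housing + r.exp_utilities + r.exp_oop_health + r.exp_other

    ranking = sorted(total(r) / r.household_size**exponent for r in rows)
    lo = _type7(ranking, window[0] / 100)
    hi = _type7(ranking, window[1] / 100)
    selected = [r for r in rows if lo <= total(r) / r.household_size**exponent <= hi]
    if not selected:
        mid = (lo + hi) / 2
        best = min(abs(total(r) / r.household_size**exponent - mid) for r in rows)
        selected = [
            r for r in rows if abs(total(r) / r.household_size**exponent - mid) == best
        ]
    vals = [
        (r.exp_food + r.exp_housing + r.exp_utilities) / r.household_size**exponent
        for r in selected
    ]
    return sum(vals) / len(vals), len(vals)


def _type7(sorted_vals, p):
    h = (len(sorted_vals) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(sorted_vals) - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


@pytest.mark.parametrize("seed", range(12))
def test_window_estimators_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    wave = make_wave(rng, int(rng.integers(5, 200)))
    est_f = estimate_normative_food(wave)
    exp_f, n_f = oracle_normative_food(wave)
    assert est_f.per_equivalent_standard == pytest.approx(exp_f, rel=1e-12)
    assert est_f.n_window_households == n_f
    est_s = estimate_normative_subsistence(wave)
    exp_s, n_s = oracle_normative_subsistence(wave)
    assert est_s.per_equivalent_standard == pytest.approx(exp_s, rel=1e-12)
    assert est_s.n_window_households == n_s


def test_raw_total_ranking_switch_changes_selection():
    """With non-singleton households the two ranking variables differ."""
    rng = np.random.default_rng(3)
    wave = make_wave(rng, 80)
    per_eq = estimate_normative_subsistence(wave, IndicatorConfig())
    raw = estimate_normative_subsistence(
        wave, IndicatorConfig(subsistence_ranking="raw_total")
    )
    assert per_eq.window_bounds != raw.window_bounds


def test_scale_invariance_of_all_flags():
    """Multiplying every monetary field by c > 0 leaves every flag unchanged."""
    rng = np.random.default_rng(11)
    wave = make_wave(rng, 150)
    base, _ = assess_households(wave)
    for c in (7.3, 0.002):
        scaled = wave.copy()
        for col in ("exp_food", "exp_housing", "exp_utilities", "exp_oop_health", "exp_other"):
            scaled[col] = scaled[col] * c
        flags_scaled, _ = assess_households(scaled)
        for method in OBJECTIVE_METHODS:
            a = base.loc[base["method"] == method, "che_flag"].reset_index(drop=True)
            b = flags_scaled.loc[flags_scaled["method"] == method, "che_flag"].reset_index(drop=True)
            pd.testing.assert_series_equal(a, b)


def test_oop_monotonicity_of_all_flags():
    """Raising OOP (total rising with it) never clears a flag."""
    rng = np.random.default_rng(13)
    wave = make_wave(rng, 120)
    base, est = assess_households(wave)
    bumped = wave.copy()
    bumped["exp_oop_health"] = bumped["exp_oop_health"] + rng.uniform(0, 400, len(bumped))
    # same wave-level estimates: the contrast is per household, standards fixed
    flags_bumped, _ = assess_households(bumped, estimates=est)
    for method in OBJECTIVE_METHODS:
        a = base.loc[base["method"] == method, "che_flag"].to_numpy()
        b = flags_bumped.loc[flags_bumped["method"] == method, "che_flag"].to_numpy()
        assert not np.any((a == 1) & (b == 0))


def test_degenerate_thresholds():
    rng = np.random.default_rng(17)
    wave = make_wave(rng, 100)
    zero_thr, _ = assess_households(
        wave, IndicatorConfig(budget_share_threshold=0.0, ctp_threshold=0.0)
    )
    for method in OBJECTIVE_METHODS:
        sub = zero_thr[zero_thr["method"] == method]
        pos = (sub["numerator"] > 0) & (sub["denominator"] > 0)
        assert (sub.loc[pos, "che_flag"] == 1).all()
    high_thr, _ = assess_households(
        wave, IndicatorConfig(budget_share_threshold=0.999999, ctp_threshold=0.999999)
    )
    sub = high_thr[high_thr["method"] == "budget_share"]
    assert (sub["che_flag"].dropna() == 0).all()


def test_zero_equivalence_exponent_means_per_household_standard():
    wave = five_household_wave()
    cfg = IndicatorConfig(equivalence_exponent=0.0)
    est = estimate_normative_food(wave, cfg)
    # all sizes 1 here, but a size-4 household now shares the same standard
    a1 = partial_normative_food_flag(10.0, 300.0, 100.0, 1, est, cfg)
    a4 = partial_normative_food_flag(10.0, 300.0, 100.0, 4, est, cfg)
    assert a1.denominator == a4.denominator


def test_incidence_matches_bruteforce_recount():
    rng = np.random.default_rng(19)
    waves = pd.concat(
        [make_wave(rng, 200, wave=2013), make_wave(rng, 150, wave=2017)],
        ignore_index=True,
    )
    waves["household_id"] = range(len(waves))
    assessments, _ = assess_households(waves)
    for rule in ("all", "oop_positive"):
        inc = compute_incidence(assessments, by=("wave",), denominator_rule=rule)
        for _, row in inc.iterrows():
            expected_n = 0
            expected_flagged = 0
            sub = assessments[
                (assessments["method"] == row["method"])
                & (assessments["wave"] == row["wave"])
            ]
            for _, r in sub.iterrows():
                if pd.isna(r["che_flag"]):
                    continue
                if rule == "oop_positive" and not r["exp_oop_health"] > 0:
                    continue
                expected_n += 1
                expected_flagged += int(r["che_flag"])
            assert row["n"] == expected_n
            assert row["n_flagged"] == expected_flagged
            assert row["incidence_pct"] == pytest.approx(
                round(100 * expected_flagged / expected_n, 2)
            )


def test_incidence_simple_counts():
    flags = pd.DataFrame(
        {
            "method": "budget_share",
            "wave": 2013,
            "exp_oop_health": 1.0,
            "che_flag": pd.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype="Int64"),
        }
    )
    inc = compute_incidence(flags, by=("wave",))
    assert inc.loc[0, "incidence_pct"] == 30.0
    flags["che_flag"] = pd.array([0] * 10, dtype="Int64")
    assert compute_incidence(flags, by=("wave",)).loc[0, "incidence_pct"] == 0.0
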