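"""Agreement between objective and self-rated CHE, and the discrepancy outcomes.

Households with both flags observed fall into a 2x2 partition per wave and
objective method: flagged by both, by neither, self-rated only, or objective
only.  Two discrepancy outcomes feed the association models:

* **outcome A** ("self-rated CHE without support from the objective
  indicator") is defined on objective-negative households and equals the
  self-rating there;
* **outcome B** ("CHE classified by the objective indicator without backup
  from self-rating") is defined on objective-positive households and equals
  one minus the self-rating there.

Outside its subpopulation each outcome is missing, so the two models run on
complementary subsamples of very different size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd

from che_gap.che_indicators import OBJECTIVE_METHODS
from che_gap.errors import ValidationError


def _round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; Python's round is banker's)."""
    factor = 10**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


@dataclass(frozen=True)
class DiscrepancyTable:
    """2x2 agreement counts for one wave x objective method."""

    wave: int
    method: str
    n_both: int
    n_neither: int
    n_self_only: int
    n_obj_only: int

    @property
    def n(self) -> int:
        return self.n_both + self.n_neither + self.n_self_only + self.n_obj_only

    def pct(self, cell: str) -> float:
        return _round_half_away(100.0 * getattr(self, cell) / self.n) if self.n else 0.0

    @property
    def consistency_pct(self) -> float:
        return (
            _round_half_away(100.0 * (self.n_both + self.n_neither) / self.n)
            if self.n
            else 0.0
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = self.n
        for cell in ("n_both", "n_neither", "n_self_only", "n_obj_only"):
            d[f"pct_{cell[2:]}"] = self.pct(cell)
        d["consistency_pct"] = self.consistency_pct
        return d


def cross_classify(
    assessments: pd.DataFrame,
    methods: tuple[str, ...] = OBJECTIVE_METHODS,
    by_wave: bool = True,
) -> list[DiscrepancyTable]:
    """Cross-classify objective against self-rated flags per wave x method.

    ``assessments`` is the long table from ``assess_households``.  Rows where
    either flag is missing are excluded from the cell counts.  Duplicate
    household keys within a wave raise an input-integrity error.
    """
    wide = _flags_wide(assessments)
    tables: list[DiscrepancyTable] = []
    group_iter = wide.groupby("wave", sort=True) if by_wave else [(0, wide)]
    for wave, grp in group_iter:
        for method in methods:
            sub = grp[[method, "self_rated"]].dropna()
            obj = sub[method].astype(int)
            self_ = sub["self_rated"].astype(int)
            tables.append(
                DiscrepancyTable(
                    wave=int(wave),
                    method=method,
                    n_both=int(((obj == 1) & (self_ == 1)).sum()),
                    n_neither=int(((obj == 0) & (self_ == 0)).sum()),
                    n_self_only=int(((obj == 0) & (self_ == 1)).sum()),
                    n_obj_only=int(((obj == 1) & (self_ == 0)).sum()),
                )
            )
    return tables


def _flags_wide(assessments: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long assessment table to one row per household."""
    dup = assessments.duplicated(subset=["household_id", "method"])
    if dup.any():
        raise ValidationError(
            f"duplicate household keys in assessments (e.g. "
            f"{assessments.loc[dup.idxmax(), 'household_id']!r})"
        )
    wide = assessments.pivot(index="household_id", columns="method", values="che_flag")
    meta = assessments.drop_duplicates("household_id").set_index("household_id")[
        [c for c in ("wave", "residency", "exp_oop_health") if c in assessments.columns]
    ]
    return meta.join(wide).reset_index()


def make_outcomes(
    assessments: pd.DataFrame, methods: tuple[str, ...] = OBJECTIVE_METHODS
) -> pd.DataFrame:
    """Build the discrepancy outcome columns, one pair per objective method.

    Returns one row per household with columns ``A_<method>`` (self-rating on
    the objective-negative subpopulation) and ``B_<method>`` (1 - self-rating
    on the objective-positive subpopulation); outside its subpopulation an
    outcome is missing.
    """
    wide = _flags_wide(assessments)
    out = wide[[c for c in ("household_id", "wave", "residency", "exp_oop_health") if c in wide.columns]].copy()
    self_ = wide["self_rated"]
    for method in methods:
        obj = wide[method]
        observed = obj.notna() & self_.notna()
        a = pd.Series(pd.NA, index=wide.index, dtype="Int64")
        b = pd.Series(pd.NA, index=wide.index, dtype="Int64")
        neg = observed & (obj == 0)
        pos = observed & (obj == 1)
        a[neg] = self_[neg].astype("Int64")
        b[pos] = (1 - self_[pos]).astype("Int64")
        out[f"A_{method}"] = a
        out[f"B_{method}"] = b
    return out


def discrepancy_frame(tables: list[DiscrepancyTable]) -> pd.DataFrame:
    """Long-format report: one row per wave x method with counts and percentages."""
    return pd.DataFrame([t.to_dict() for t in tables])
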