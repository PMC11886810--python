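"""End-to-end orchestration: simulate -> prepare -> indicators -> discrepancy -> regress.

``run_pipeline`` chains the five stages, writes every intermediate artifact
as CSV or JSON (diffable text only), and records a manifest with the
configuration hash, seed, and per-stage record counts, so a run is a pure
function of (input file, configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from che_gap import synthetic_data
from che_gap.association_models import DEFAULT_COVARIATES, fit_logit, icc_diagnostic
from che_gap.che_indicators import (
    OBJECTIVE_METHODS,
    assess_households,
    compute_incidence,
)
from che_gap.cohort_prep import apply_exclusions, build_covariates
from che_gap.config import IndicatorConfig, SimConfig, config_to_dict
from che_gap.discrepancy import cross_classify, discrepancy_frame, make_outcomes
from che_gap.errors import ConfigurationError

logger = logging.getLogger(__name__)

ALL_MODELS = tuple(
    f"{side}:{method}" for side in ("A", "B") for method in OBJECTIVE_METHODS
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "che_gap_run"
    input_path: str | Path | None = None  # read records here instead of simulating
    sim: SimConfig | None = None
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    incidence_denominator: str = "oop_positive"  # or "all"
    models: tuple[str, ...] = ("all",)
    include_icc: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.incidence_denominator not in ("all", "oop_positive"):
            raise ConfigurationError(
                f"incidence_denominator must be 'all' or 'oop_positive', "
                f"got {self.incidence_denominator!r}"
            )
        if self.input_path is None and self.sim is None:
            # default simulation with the run seed
            pass
        for m in self.resolve_models():
            side, _, method = m.partition(":")
            if side not in ("A", "B") or method not in OBJECTIVE_METHODS:
                raise ConfigurationError(f"unknown model id {m!r}")
        self.indicators.validate()

    def resolve_models(self) -> tuple[str, ...]:
        return ALL_MODELS if "all" in self.models else tuple(self.models)


def _config_hash(config: RunConfig) -> str:
    payload = {
        "indicators": config_to_dict(config.indicators),
        "sim": config_to_dict(config.sim) if config.sim else None,
        "incidence_denominator": config.incidence_denominator,
        "models": list(config.resolve_models()),
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; return the report bundle as a dict of artifacts.

    Artifacts are also written under ``config.out_dir``: the simulated or
    loaded records, the exclusion log, per-wave normative estimates,
    incidence tables (overall and by urban/rural residency), the 2x2
    discrepancy tables, the model results, the ICC diagnostics, and a
    manifest listing every stage with its input/output counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    # Stage 1: simulate or load
    if config.input_path is not None:
        records = synthetic_data.read_records(config.input_path)
        source = str(config.input_path)
    else:
        sim = config.sim or SimConfig(seed=config.seed)
        records = synthetic_data.generate_population(sim)
        synthetic_data.write_records(records, out / "records.csv")
        source = "simulated"
    stages.append({"stage": "simulate/load", "source": source, "n_out": len(records)})

    # Stage 2: prepare (exclusions + covariates)
    retained, exclusion_log = apply_exclusions(records)
    covariates, cutoffs = build_covariates(retained)
    _write_json(exclusion_log.to_dict(), out / "exclusion_log.json")
    _write_json(
        {
            f"{var}@{wave}": list(c.cutpoints)
            for (var, wave), c in sorted(cutoffs.items())
        },
        out / "xtile_cutoffs.json",
    )
    stages.append(
        {"stage": "prepare", "n_in": len(records), "n_out": len(retained),
         "excluded_age": exclusion_log.excluded_age,
         "excluded_unaffordable_zero_oop": exclusion_log.excluded_unaffordable_zero_oop}
    )

    # Stage 3: indicators
    assessments, estimates = assess_households(retained, config.indicators)
    assessments.to_csv(out / "assessments.csv", index=False)
    _write_json(
        {
            f"{kind}@{wave}": {
                "per_equivalent_standard": est.per_equivalent_standard,
                "n_window_households": est.n_window_households,
                "window_bounds": list(est.window_bounds),
            }
            for (wave, kind), est in sorted(estimates.items())
        },
        out / "normative_estimates.json",
    )
    incidence = compute_incidence(
        assessments, by=("wave",), denominator_rule=config.incidence_denominator
    )
    incidence_res = compute_incidence(
        assessments, by=("wave", "residency"),
        denominator_rule=config.incidence_denominator,
    )
    incidence.to_csv(out / "incidence.csv", index=False)
    incidence_res.to_csv(out / "incidence_by_residency.csv", index=False)
    stages.append({"stage": "indicators", "n_in": len(retained),
                   "n_out": int(assessments["household_id"].nunique())})

    # Stage 4: discrepancy
    tables = cross_classify(assessments)
    disc = discrepancy_frame(tables)
    disc.to_csv(out / "discrepancy.csv", index=False)
    outcomes = make_outcomes(assessments)
    stages.append({"stage": "discrepancy", "n_tables": len(tables)})

    # Stage 5: regression models
    analysis = covariates.merge(
        outcomes.drop(columns=[c for c in ("wave", "residency", "exp_oop_health") if c in outcomes]),
        on="household_id",
        how="left",
    )
    model_results = {}
    icc_results = {}
    for model_id in config.resolve_models():
        side, _, method = model_id.partition(":")
        outcome_col = f"{side}_{method}"
        result = fit_logit(analysis, outcome_col, DEFAULT_COVARIATES)
        model_results[model_id] = result.to_dict()
        if config.include_icc:
            icc_results[model_id] = icc_diagnostic(
                analysis, outcome_col, model_id=model_id
            ).to_dict()
    _write_json(model_results, out / "models.json")
    if config.include_icc:
        _write_json(icc_results, out / "icc.json")
    stages.append({"stage": "regress", "n_models": len(model_results)})

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "incidence_denominator": config.incidence_denominator,
        "stages": stages,
    }
    _write_json(manifest, out / "manifest.json")

    bundle = {
        "records": records,
        "retained": retained,
        "exclusion_log": exclusion_log,
        "covariates": covariates,
        "cutoffs": cutoffs,
        "assessments": assessments,
        "estimates": estimates,
        "incidence": incidence,
        "incidence_by_residency": incidence_res,
        "discrepancy": disc,
        "outcomes": outcomes,
        "analysis": analysis,
        "models": model_results,
        "icc": icc_results,
        "manifest": manifest,
    }
    logger.info("pipeline complete: %d stages, %d models", len(stages), len(model_results))
    return bundle
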