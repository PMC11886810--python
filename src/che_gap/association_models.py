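"""Logistic models of factors associated with the CHE discrepancy outcomes.

For each discrepancy outcome (self-rated CHE without objective support, and
objective CHE without self-rated backup, one pair per objective method) a
single-level maximum-likelihood logistic regression is fitted on the
categorized covariates, reporting adjusted odds ratios (exponentiated
coefficients) with 95% Wald confidence intervals, McFadden's pseudo-R² and
the AIC.  Two-sided p < 0.1 is starred as significant (*, ** and *** at 0.1,
0.05 and 0.01).  Crude odds ratios come from single-term fits of the same
machinery, and a continuous-form variant re-fits each model with the
untransformed numeric versions of the x-tiled covariates as a robustness
check.

Whether provincial clustering warrants multi-level modelling is decided by a
null random-intercept logistic model: the intraclass correlation on the
latent-logistic scale is v / (v + pi^2/3), where v is the between-province
intercept variance, and values below the conventional 0.059 threshold favour
single-level models.  The random-intercept likelihood is integrated with
fixed-order Gauss-Hermite quadrature, so the diagnostic is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from che_gap.cohort_prep import (
    CONTINUOUS_SUBSTITUTES,
    PASSTHROUGH_LEVELS,
    REFERENCE_LEVELS,
    XTILE_SPECS,
    per_model_deletion,
)
from che_gap.errors import ModelInfeasibleError

ICC_SINGLE_LEVEL_THRESHOLD = 0.059
GH_QUADRATURE_NODES = 25

#: Covariates of the main (categorical-form) models, in report order.
DEFAULT_COVARIATES = (
    "household_size_cat",
    "gender_ratio_cat",
    "aged_care_need",
    "childcare_need",
    "education_highest",
    "income_quintile",
    "perceived_class",
    "prop_nonworking_cat",
    "unemployment_any",
    "residency",
    "hukou_not_aligned",
    "insurance",
    "health_budget_cat",
    "region",
    "wave",
)

_LEVEL_ORDER = {
    **{name: labels for name, (_, _, labels) in XTILE_SPECS.items()},
    **PASSTHROUGH_LEVELS,
}
# x-tile columns are named after the derived covariate, not the source.
_LEVEL_ORDER = {
    "household_size_cat": XTILE_SPECS["household_size_cat"][2],
    "gender_ratio_cat": XTILE_SPECS["gender_ratio_cat"][2],
    "income_quintile": XTILE_SPECS["income_quintile"][2],
    "prop_nonworking_cat": XTILE_SPECS["prop_nonworking_cat"][2],
    "health_budget_cat": XTILE_SPECS["health_budget_cat"][2],
    **PASSTHROUGH_LEVELS,
}

_BINARY_TERMS = ("aged_care_need", "childcare_need", "unemployment_any", "hukou_not_aligned")


def significance_stars(p_value: float) -> str:
    """Printed convention: * p<0.1, ** p<0.05, *** p<0.01 (two-sided)."""
    if p_value < 0.01:
        return "***"
    if p_value < 0.05:
        return "**"
    if p_value < 0.1:
        return "*"
    return ""


@dataclass
class ModelResult:
    """A fitted logistic model: AOR table plus fit statistics."""

    outcome: str
    n_used: int
    coefficients: pd.DataFrame
    pseudo_r2: float
    aic: float
    log_likelihood: float
    converged: bool
    dropped_terms: list = field(default_factory=list)
    deletion_report: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_used": self.n_used,
            "pseudo_r2": round(self.pseudo_r2, 4),
            "aic": round(self.aic, 3),
            "log_likelihood": round(self.log_likelihood, 3),
            "converged": self.converged,
            "dropped_terms": list(self.dropped_terms),
            "deletion_report": dict(self.deletion_report),
            "coefficients": self.coefficients.to_dict(orient="records"),
        }


def _design_matrix(table: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list]:
    """Dummy-code the covariates against their reference levels.

    Categorical terms contribute one indicator per non-reference level, named
    ``term[level]``; binary and continuous terms contribute themselves.
    All-constant columns (a level absent from the subsample) are dropped and
    reported, mirroring the "cannot generate results" case in sparse
    subpopulations.
    """
    cols: dict[str, np.ndarray] = {}
    for term in covariates:
        if term == "wave":
            ref = int(table["wave"].min())
            for level in sorted(table["wave"].astype(int).unique()):
                if level != ref:
                    cols[f"wave[{level}]"] = (table["wave"].astype(int) == level).to_numpy(float)
        elif term in _LEVEL_ORDER:
            levels = _LEVEL_ORDER[term]
            ref = REFERENCE_LEVELS[term]
            for level in levels:
                if level != ref:
                    cols[f"{term}[{level}]"] = (table[term] == level).to_numpy(float)
        elif term in _BINARY_TERMS:
            cols[term] = table[term].astype(float).to_numpy()
        else:  # continuous
            cols[term] = table[term].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=table.index)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    # sparse-cell guard: an indicator supported by <5 rows cannot be estimated
    # (the "cannot generate results" case in small subpopulations)
    for c in X.columns:
        vals = X[c]
        if c not in dropped and set(vals.unique()) <= {0.0, 1.0}:
            if min(vals.sum(), (1 - vals).sum()) < 5:
                dropped.append(c)
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ModelInfeasibleError("no non-constant covariate columns remain")
    return X, dropped


def fit_logit(
    table: pd.DataFrame,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    form: str = "categorical",
) -> ModelResult:
    """Fit one multivariate logistic model for a discrepancy outcome.

    Rows incomplete on the outcome or any covariate are dropped for this
    model only (per-model deletion).  ``form="continuous_robustness"``
    substitutes the untransformed numeric variables for the x-tiled
    categorical ones.  Quasi-separated terms are reported with a fit-failure
    flag in the coefficient table rather than allowed to diverge silently.
    """
    covariates = list(covariates)
    if form == "continuous_robustness":
        covariates = [CONTINUOUS_SUBSTITUTES.get(c, c) for c in covariates]
    elif form != "categorical":
        raise ModelInfeasibleError(f"unknown model form {form!r}")

    analysis, report = per_model_deletion(table, outcome, covariates)
    y = analysis[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ModelInfeasibleError(f"outcome {outcome!r} takes a single level")
    X, dropped = _design_matrix(analysis, covariates)
    X = sm.add_constant(X, prepend=True)

    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, Exception) as exc:  # separation, singular hessian
        raise ModelInfeasibleError(f"logistic fit failed for {outcome!r}: {exc}") from exc

    params = res.params
    bse = res.bse
    pvals = res.pvalues
    z = 1.959963984540054  # 95% normal quantile
    rows = []
    for name in X.columns:
        if name == "const":
            continue
        coef = float(params[name])
        se = float(bse[name])
        fit_failed = not np.isfinite(se) or se > 50 or abs(coef) > 15
        _exp = lambda v: float(np.exp(np.clip(v, -745, 709)))  # avoid overflow on separated terms
        rows.append(
            {
                "term": name.split("[")[0],
                "level": name.split("[")[1].rstrip("]") if "[" in name else "",
                "coef": coef,
                "se": se,
                "aor": _exp(coef),
                "ci_low": _exp(coef - z * se),
                "ci_high": _exp(coef + z * se),
                "p_value": float(pvals[name]),
                "stars": significance_stars(float(pvals[name])),
                "fit_failed": fit_failed,
            }
        )
    coef_table = pd.DataFrame(rows)
    return ModelResult(
        outcome=outcome,
        n_used=int(report["n_used"]),
        coefficients=coef_table,
        pseudo_r2=float(res.prsquared),
        aic=float(res.aic),
        log_likelihood=float(res.llf),
        converged=converged,
        dropped_terms=dropped,
        deletion_report=report,
    )


def fit_crude(table: pd.DataFrame, outcome: str, term: str) -> ModelResult:
    """Crude (single-term) odds ratios: the same contract as ``fit_logit``."""
    return fit_logit(table, outcome, [term])


@dataclass
class IccDiagnostic:
    """Null random-intercept diagnostics for the single- vs multi-level choice."""

    model_id: str
    variance_between_provinces: float
    icc: float
    aic_single: float
    aic_multilevel: float
    recommendation: str
    converged: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "variance_between_provinces": round(self.variance_between_provinces, 6),
            "icc": round(self.icc, 6),
            "aic_single": round(self.aic_single, 3),
            "aic_multilevel": round(self.aic_multilevel, 3),
            "recommendation": self.recommendation,
            "converged": self.converged,
            "reason": self.reason,
        }


def icc_from_variance(variance: float) -> float:
    """Latent-logistic intraclass correlation: v / (v + pi^2/3)."""
    if variance < 0:
        raise ModelInfeasibleError("between-cluster variance must be >= 0")
    return variance / (variance + math.pi**2 / 3.0)


def _random_intercept_null_loglik(
    theta: np.ndarray, n_j: np.ndarray, s_j: np.ndarray, nodes: np.ndarray, weights: np.ndarray
) -> float:
    """Marginal log-likelihood of the intercept-only random-intercept logit.

    Clusters share a single linear predictor b0 + u, u ~ N(0, sigma^2), so a
    cluster's conditional likelihood depends only on (n_j, successes s_j).
    The integral over u uses adaptive Gauss-Hermite quadrature: nodes are
    centred at each cluster's posterior mode and scaled by the local
    curvature, so large clusters (whose integrand is far narrower than the
    prior) are still resolved.
    """
    b0, log_sigma = theta
    sigma = max(math.exp(log_sigma), 1e-8)
    inv_v = 1.0 / sigma**2

    def g_parts(u):
        eta = b0 + u
        log_p = -np.logaddexp(0.0, -eta)
        log_q = -np.logaddexp(0.0, eta)
        g = (
            s_j * log_p
            + (n_j - s_j) * log_q
            - 0.5 * u**2 * inv_v
            - math.log(sigma)
            - 0.5 * math.log(2 * math.pi)
        )
        p = special.expit(eta)
        grad = s_j - n_j * p - u * inv_v
        hess = -n_j * p * (1 - p) - inv_v
        return g, grad, hess

    # Newton iterations to the per-cluster posterior mode (1-D, concave)
    u_hat = np.zeros_like(n_j, dtype=float)
    for _ in range(50):
        _, grad, hess = g_parts(u_hat)
        step = grad / hess
        u_hat = u_hat - step
        if np.max(np.abs(step)) < 1e-10:
            break
    _, _, hess = g_parts(u_hat)
    tau = 1.0 / np.sqrt(-hess)  # local scale at the mode

    # adaptive nodes u_jm = u_hat_j + sqrt(2) tau_j x_m
    u_nodes = u_hat[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = b0 + u_nodes
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    g = (
        s_j[:, None] * log_p
        + (n_j - s_j)[:, None] * log_q
        - 0.5 * u_nodes**2 * inv_v
        - math.log(sigma)
        - 0.5 * math.log(2 * math.pi)
    )
    log_terms = g + np.log(weights)[None, :] + nodes[None, :] ** 2
    log_int = (
        0.5 * math.log(2.0) + np.log(tau) + special.logsumexp(log_terms, axis=1)
    )
    return float(log_int.sum())


def icc_diagnostic(
    table: pd.DataFrame,
    outcome: str,
    province_col: str = "province_id",
    model_id: str | None = None,
    n_nodes: int = GH_QUADRATURE_NODES,
) -> IccDiagnostic:
    """Compare the single-level null model with a province random-intercept null.

    Reports the between-province variance on the latent scale, the ICC
    v/(v + pi^2/3), both AICs, and the modelling recommendation per the 0.059
    convention.  Deterministic: the random-intercept likelihood uses
    fixed-order Gauss-Hermite quadrature and a seedless optimizer.
    """
    model_id = model_id or outcome
    sub = table[[outcome, province_col]].dropna()
    y = sub[outcome].astype(float).to_numpy()
    prov = sub[province_col].to_numpy()
    if len(np.unique(prov)) < 2:
        raise ModelInfeasibleError("ICC diagnostic needs observations from >= 2 provinces")
    if len(np.unique(y)) < 2:
        raise ModelInfeasibleError(f"outcome {outcome!r} takes a single level")

    grp = pd.DataFrame({"y": y, "prov": prov}).groupby("prov")["y"]
    n_j = grp.count().to_numpy(dtype=float)
    s_j = grp.sum().to_numpy(dtype=float)

    # Single-level null
    n, s = n_j.sum(), s_j.sum()
    p_hat = s / n
    llf_single = s * math.log(p_hat) + (n - s) * math.log(1 - p_hat)
    aic_single = 2 * 1 - 2 * llf_single

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    b0_start = math.log(p_hat / (1 - p_hat))
    result = optimize.minimize(
        lambda th: -_random_intercept_null_loglik(th, n_j, s_j, nodes, weights),
        x0=np.array([b0_start, math.log(0.3)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if not result.success:
        return IccDiagnostic(
            model_id=model_id,
            variance_between_provinces=float("nan"),
            icc=float("nan"),
            aic_single=aic_single,
            aic_multilevel=float("nan"),
            recommendation="undetermined",
            converged=False,
            reason=str(result.message),
        )
    sigma = math.exp(result.x[1])
    variance = sigma**2
    llf_ml = -float(result.fun)
    icc = icc_from_variance(variance)
    return IccDiagnostic(
        model_id=model_id,
        variance_between_provinces=variance,
        icc=icc,
        aic_single=aic_single,
        aic_multilevel=2 * 2 - 2 * llf_ml,
        recommendation=(
            "single_level" if icc < ICC_SINGLE_LEVEL_THRESHOLD else "multilevel"
        ),
        converged=True,
    )
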