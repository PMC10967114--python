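"""Multilevel mixed-effects logistic regressions for the locum exposure.

Two designs mirror the two analysis sets: one random consultation per
patient per financial year with practice random intercepts (clinical-practice
outcomes), and repeated index consultations with practice and
patient-within-practice random intercepts (prescribing-safety indicators).
Both adjust for gender, age, multimorbidity score, years registered,
practice list size and deprivation quintile, with region and financial-year
fixed-effect indicators (deprivation enters ordinally by default).

Confidence intervals default to the 95% level printed in the published
tables; significance flags additionally honour the declared 1% alpha.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .glmm import fit_logistic_mixed

DEFAULT_COVARIATES = (
    "gender", "age", "cm_score", "years_registered", "list_size", "imd_quintile",
)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, adjustment set, nesting and CI level."""

    outcome: str
    covariates: tuple = DEFAULT_COVARIATES
    region_effects: bool = True
    year_effects: bool = True
    random_levels: tuple = ("practice",)
    ci_level: float = 0.95
    alpha: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class FitResult:
    """Locum odds ratio with uncertainty from one model fit."""

    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    p_value: float
    significant: bool
    converged: bool
    n_obs: int
    n_groups: dict
    sigmas: dict
    ci_level: float = 0.95
    message: str = ""

    def rendered(self) -> str:
        return f"{self.odds_ratio:.2f} ({self.ci_low:.2f} to {self.ci_high:.2f})"


def _design(table: pd.DataFrame, spec: ModelSpec):
    df = table.copy()
    if spec.outcome not in df.columns:
        raise EstimationError(f"outcome {spec.outcome!r} not in table")
    needed = [spec.outcome, "locum", "practice_id"] + [
        c for c in spec.covariates if c != "gender"
    ]
    if "gender" in spec.covariates:
        needed.append("gender")
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if df.empty:
        raise EstimationError("no complete-case observations")
    y = df[spec.outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise EstimationError(
            f"outcome {spec.outcome!r} has a single class; model not estimable"
        )

    cols = {"intercept": np.ones(len(df)), "locum": df["locum"].to_numpy(float)}
    for cov in spec.covariates:
        if cov == "gender":
            cols["female"] = (df["gender"] == "F").to_numpy(float)
        else:
            x = df[cov].to_numpy(float)
            sd = x.std()
            cols[cov] = (x - x.mean()) / sd if sd > 0 else np.zeros(len(df))
    for factor, use in (("region", spec.region_effects), ("fy", spec.year_effects)):
        if use and factor in df.columns and df[factor].nunique() > 1:
            dummies = pd.get_dummies(df[factor], prefix=factor, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(float)

    names = [k for k in cols if k == "intercept" or np.std(cols[k]) > 0]
    X = np.column_stack([cols[k] for k in names])

    groups, group_names = [], []
    for level in spec.random_levels:
        key = {"practice": "practice_id", "patient": "patient_id"}[level]
        codes, uniques = pd.factorize(df[key], sort=True)
        groups.append(codes)
        group_names.append((level, len(uniques)))
    return y, X, names, groups, group_names, df


def _fit(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    y, X, names, groups, group_names, df = _design(table, spec)
    fit = fit_logistic_mixed(y, X, groups, names=names)
    j = names.index("locum")
    log_or = float(fit.beta[j])
    se = float(fit.se[j])
    z = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    p = 2.0 * stats.norm.sf(abs(log_or) / se) if se > 0 else float("nan")
    with np.errstate(over="ignore"):
        # separation can push the estimate to +/- infinity on the odds scale;
        # such fits are flagged via converged=False, never silently replaced
        odds_ratio = float(np.exp(log_or))
        ci_low = float(np.exp(log_or - z * se))
        ci_high = float(np.exp(log_or + z * se))
    return FitResult(
        outcome=spec.outcome,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        log_or=log_or,
        se=se,
        p_value=p,
        significant=bool(p < spec.alpha),
        converged=fit.converged,
        n_obs=fit.n_obs,
        n_groups=dict(group_names),
        sigmas={lvl: float(s) for (lvl, _), s in zip(group_names, fit.sigmas)},
        ci_level=spec.ci_level,
        message=fit.message,
    )


def fit_patient_level(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Design 1: one sampled consultation per patient-year, practice random
    intercepts. Non-convergence and separation are flagged on the result;
    single-class outcomes raise EstimationError."""
    if spec.random_levels != ("practice",):
        spec = replace(spec, random_levels=("practice",))
    return _fit(table, spec)


def fit_indicator_level(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Design 2: repeated index consultations nested within patients within
    practices (practice and patient random intercepts)."""
    if spec.random_levels != ("practice", "patient"):
        spec = replace(spec, random_levels=("practice", "patient"))
    return _fit(table, spec)


def sensitivity_exclude_years(
    table: pd.DataFrame,
    years_to_drop,
    specs,
    fitter=fit_patient_level,
) -> pd.DataFrame:
    """Refit every model on the table restricted to the remaining financial
    years (e.g. dropping the last three years to probe the pandemic period);
    returns full-vs-restricted estimate pairs."""
    years_to_drop = set(years_to_drop)
    present = set(table["fy"])
    restricted = table[~table["fy"].isin(years_to_drop)]
    if restricted.empty:
        raise EstimationError("excluding those years leaves no data")
    rows = []
    for spec in specs:
        full = fitter(table, spec)
        part = fitter(restricted, spec) if years_to_drop & present else full
        rows.append(
            {
                "outcome": spec.outcome,
                "or_full": full.odds_ratio,
                "ci_low_full": full.ci_low,
                "ci_high_full": full.ci_high,
                "or_restricted": part.odds_ratio,
                "ci_low_restricted": part.ci_low,
                "ci_high_restricted": part.ci_high,
                "n_full": full.n_obs,
                "n_restricted": part.n_obs,
            }
        )
    return pd.DataFrame(rows)


def report_or_table(fits) -> pd.DataFrame:
    """Published-table-shaped report: OR (CI), p, SE per outcome."""
    fits = list(fits)
    if not fits:
        raise EstimationError("no fits to report")
    return pd.DataFrame(
        [
            {
                "outcome": f.outcome,
                "odds_ratio": f.odds_ratio,
                "ci_low": f.ci_low,
                "ci_high": f.ci_high,
                "p_value": f.p_value,
                "se": f.se,
                "rendered": f.rendered(),
                "converged": f.converged,
                "n_obs": f.n_obs,
            }
            for f in fits
        ]
    )


def plot_data(fits) -> pd.DataFrame:
    """Coefficient-plot export: OR and CI per outcome with a flag for
    intervals crossing 1 (not significant at the CI level)."""
    fits = list(fits)
    if not fits:
        raise EstimationError("no fits to export")
    return pd.DataFrame(
        [
            {
                "outcome": f.outcome,
                "odds_ratio": f.odds_ratio,
                "ci_low": f.ci_low,
                "ci_high": f.ci_high,
                "significant": bool(f.ci_low > 1.0 or f.ci_high < 1.0),
            }
            for f in fits
        ]
    )
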