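"""Two-step clinical variable selection.

First screen: each candidate variable is tested marginally with a log-rank
test (continuous variables are median-split into high/low groups, as is
conventional when drawing Kaplan-Meier curves for a continuous marker).
Second screen: backward stepwise elimination from the full multivariable
Cox model.  Multi-level categorical factors enter and leave as a unit, so
a factor is never left with a dangling subset of its dummy columns.

The stepwise criterion is AIC by default; a p-value mode (drop the least
significant unit while its Wald p exceeds a threshold) is available via
``criterion="p_value"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import CoxFit, fit_cox
from .datasets import SurvivalDataset
from .exceptions import DomainError, EmptyInputError
from .nonparametric import logrank_test

__all__ = ["ScreenReport", "km_screen", "backward_stepwise_cox", "build_design"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Outcome of one marginal screen: keep iff p < alpha (degenerate
    variables are always dropped and flagged)."""

    variable: str
    statistic: float
    p_value: float
    decision: str  # "keep" | "drop"
    split_rule: str  # "levels" for categoricals, "median split at <m>" for continuous
    degenerate: bool = False


def _is_categorical(series: pd.Series, schema: Optional[dict], name: str) -> bool:
    if schema and name in schema:
        return schema[name] == "categorical"
    return not pd.api.types.is_numeric_dtype(series)


def build_design(
    clinical: pd.DataFrame,
    variables: Sequence[str],
    schema: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand variables into a numeric design matrix.

    Categorical variables become treatment-coded dummies against the first
    (sorted) level; continuous variables pass through.  Returns the design
    and a map variable -> its design columns, which the stepwise search
    uses to remove factors as units.
    """
    cols = {}
    groups: dict[str, list[str]] = {}
    for name in variables:
        if name not in clinical.columns:
            raise DomainError(f"variable not in clinical table: {name}")
        s = clinical[name]
        if _is_categorical(s, schema, name):
            levels = sorted(pd.unique(s.dropna().astype(str)))
            members = []
            for lev in levels[1:]:
                col = f"{name}_{lev}"
                cols[col] = (s.astype(str) == lev).astype(float)
                members.append(col)
            groups[name] = members
        else:
            cols[name] = s.astype(float)
            groups[name] = [name]
    design = pd.DataFrame(cols, index=clinical.index)
    return design, groups


def km_screen(
    dataset: SurvivalDataset,
    variables: Sequence[str],
    alpha: float = 0.05,
    schema: Optional[dict] = None,
) -> list[ScreenReport]:
    """Marginal Kaplan-Meier / log-rank screen of clinical variables.

    Categorical variables are tested across their observed levels;
    continuous variables are dichotomized at the sample median.  A constant
    (or unsplittable) variable is reported as degenerate and dropped.
    """
    if not 0 < alpha <= 1:
        raise DomainError("alpha must lie in (0, 1]")
    time, status = dataset.time, dataset.status
    clinical = dataset.clinical
    reports = []
    for name in variables:
        if name not in clinical.columns:
            raise DomainError(f"variable not in clinical table: {name}")
        s = clinical[name]
        mask = s.notna().to_numpy()
        if _is_categorical(s, schema, name):
            grp = s[mask].astype(str).to_numpy()
            rule = "levels"
        else:
            vals = s[mask].to_numpy(dtype=float)
            med = float(np.median(vals)) if vals.size else np.nan
            grp = np.where(vals > med, "high", "low")
            rule = f"median split at {med:.6g}"
        if np.unique(grp).size < 2:
            reports.append(ScreenReport(name, np.nan, np.nan, "drop", rule, degenerate=True))
            continue
        stat, p = logrank_test(time[mask], status[mask], grp)
        decision = "keep" if p < alpha else "drop"
        reports.append(ScreenReport(name, stat, p, decision, rule))
    return reports


def _fit_units(
    design: pd.DataFrame, groups: dict[str, list[str]], units: list[str], time, status
) -> CoxFit:
    cols = [c for u in units for c in groups[u]]
    if not cols:
        return fit_cox(np.empty((len(time), 0)), time, status)
    return fit_cox(design[cols], time, status)


def backward_stepwise_cox(
    dataset: SurvivalDataset,
    variables: Sequence[str],
    criterion: str = "aic",
    p_remove: float = 0.05,
    schema: Optional[dict] = None,
) -> tuple[CoxFit, list[str]]:
    """Backward stepwise elimination from the full multivariable Cox model.

    With ``criterion="aic"`` the unit (whole factor or single continuous
    variable) whose removal lowers AIC the most is dropped until no removal
    improves AIC.  With ``criterion="p_value"`` the least significant unit
    (Wald chi-square across its columns) is dropped while its p exceeds
    ``p_remove``.  Returns the refitted final model and the surviving
    variable names; an empty selection yields the null model.
    """
    if not variables:
        raise DomainError("need at least one candidate variable")
    if criterion not in ("aic", "p_value"):
        raise DomainError(f"unknown criterion: {criterion}")
    clinical = dataset.clinical
    keep_rows = clinical[list(variables)].notna().all(axis=1).to_numpy()
    if keep_rows.sum() < len(clinical):
        logger.info("backward_stepwise_cox: dropped %d rows with missing covariates",
                    int((~keep_rows).sum()))
    clinical = clinical.loc[keep_rows]
    time, status = dataset.time[keep_rows], dataset.status[keep_rows]
    design, groups = build_design(clinical, variables, schema)
    # constant columns cannot enter a Cox fit; treat as degenerate units
    units = []
    for v in variables:
        member_cols = groups[v]
        if member_cols and all(design[c].nunique() > 1 for c in member_cols):
            units.append(v)
        else:
            logger.info("backward_stepwise_cox: excluding degenerate variable %s", v)
    if status.sum() < sum(len(groups[u]) for u in units):
        raise DomainError("fewer events than parameters in the full model")

    current = _fit_units(design, groups, units, time, status)
    while units:
        if criterion == "aic":
            best_unit, best_fit, best_aic = None, None, current.aic
            for u in units:
                cand = _fit_units(design, groups, [v for v in units if v != u], time, status)
                if cand.aic < best_aic - 1e-10:
                    best_unit, best_fit, best_aic = u, cand, cand.aic
            if best_unit is None:
                break
            units = [v for v in units if v != best_unit]
            current = best_fit
        else:
            worst_unit, worst_p = None, -1.0
            for u in units:
                p = _wald_unit_p(current, groups[u])
                if p > worst_p:
                    worst_unit, worst_p = u, p
            if worst_p <= p_remove:
                break
            units = [v for v in units if v != worst_unit]
            current = _fit_units(design, groups, units, time, status)
    return current, units


def _wald_unit_p(fit: CoxFit, cols: list[str]) -> float:
    """Joint Wald chi-square p-value for a block of coefficients."""
    idx = [fit.names.index(c) for c in cols]
    b = fit.coefficients.to_numpy()[idx]
    V = fit.covariance.to_numpy()[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        stat = float(b @ np.linalg.pinv(V) @ b)
    return float(stats.chi2.sf(stat, len(cols)))


def screen_reports_frame(reports: list[ScreenReport]) -> pd.DataFrame:
    """Screen reports as a writable table (variable, statistic, p, decision)."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in reports],
            "statistic": [r.statistic for r in reports],
            "p_value": [r.p_value for r in reports],
            "decision": [r.decision for r in reports],
            "split_rule": [r.split_rule for r in reports],
        }
    )
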