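"""Landmark dynamic prediction with a stacked supermodel.

For each landmark time s in a grid, the subjects still at risk at s form
a landmark dataset, administratively censored at s + w (the prediction
window).  Concatenating these datasets gives the "super prediction
dataset"; a single delayed-entry Cox fit on it — entry at s, risk sets
pooled across landmarks, one common baseline hazard (the ipl*
formulation) — yields a supermodel whose coefficients are smooth in s:

    linear predictor at (s, x) =
        gamma1 * (s/tau) + gamma2 * (s/tau)^2 + (beta0 + beta1 * s/tau) * x,

with x the subject's combined prognostic index frozen at baseline.  The
fixed-width conditional mortality is then

    F_w(s | x) = 1 - exp(-[H0(s + w) - H0(s)] * exp(linear predictor)),

the probability of dying within w years given being alive at s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stepfun import StepFunction
from .coxph import CoxFit, fit_cox
from .datasets import SurvivalDataset, unpack_survival
from .exceptions import ConfigurationError, DomainError, EmptyInputError

__all__ = [
    "LandmarkConfig",
    "build_landmark_stack",
    "SupermodelFit",
    "fit_supermodel_ipl_star",
    "evaluate_effect",
    "dynamic_window_mortality",
    "mortality_curves",
    "LandmarkSupermodel",
]

_BASIS_COLS = ["s_tau", "s_tau_sq", "x", "x_s_tau"]


@dataclass
class LandmarkConfig:
    """Landmark grid (default 0-7 years inclusive, step 0.1 => 71
    landmarks), window width w (default 5 years) and scaling horizon tau
    (default 7 years; divides s in every basis term)."""

    s_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 7.0 + 1e-9, 0.1), 10))
    w: float = 5.0
    tau: float = 7.0

    def validate(self):
        s = np.asarray(self.s_grid, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ConfigurationError("s_grid must be a non-empty 1-d array")
        if np.any(np.diff(s) <= 0):
            raise ConfigurationError("s_grid must be strictly increasing")
        if s[0] < 0:
            raise ConfigurationError("s_grid must be non-negative")
        if self.w <= 0:
            raise ConfigurationError("window width w must be positive")
        if self.tau < s[-1]:
            raise ConfigurationError("tau must be at least max(s_grid)")


def build_landmark_stack(
    dataset: SurvivalDataset, cvpi_comb: pd.Series, config: Optional[LandmarkConfig] = None
) -> pd.DataFrame:
    """Build the super prediction dataset.

    For every landmark s, each subject with observed time T > s contributes
    one record (entry = s, exit = min(T, s + w), window event indicator
    status_w = 1 iff the event occurred with T <= s + w), with the combined
    index frozen at baseline and the basis columns s/tau, (s/tau)^2 and
    x * s/tau attached.  Record count = sum_s #{i : T_i > s}.
    """
    config = config or LandmarkConfig()
    config.validate()
    cvpi_comb = pd.Series(cvpi_comb)
    missing = [i for i in dataset.subject_id if i not in cvpi_comb.index]
    if missing:
        raise DomainError(f"cvpi_comb missing {len(missing)} subjects (e.g. {missing[:3]})")
    x_all = cvpi_comb.loc[dataset.subject_id].to_numpy(dtype=float)
    time, status = dataset.time, dataset.status

    frames = []
    for s in np.asarray(config.s_grid, dtype=float):
        at_risk = time > s
        if not at_risk.any():
            continue
        T = time[at_risk]
        exit_ = np.minimum(T, s + config.w)
        status_w = ((T <= s + config.w) & (status[at_risk] == 1)).astype(int)
        x = x_all[at_risk]
        st = s / config.tau
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": dataset.subject_id[at_risk],
                    "s": s,
                    "entry": s,
                    "exit": exit_,
                    "status_w": status_w,
                    "x": x,
                    "s_tau": st,
                    "s_tau_sq": st**2,
                    "x_s_tau": x * st,
                }
            )
        )
    if not frames:
        raise EmptyInputError("empty landmark stack: no subject at risk at any landmark")
    return pd.concat(frames, ignore_index=True)


@dataclass
class SupermodelFit:
    """Fitted ipl* landmark supermodel.

    gamma1, gamma2 scale the landmark baseline terms s/tau and (s/tau)^2;
    beta0 is the main effect of the combined index and beta1 its
    landmark-linear interaction, so the index coefficient at landmark s is
    beta0 + beta1 * s/tau.  ``baseline_cumhaz`` is the Breslow estimator
    from the stacked fit; ``robust_covariance`` (optional) is the
    cluster-sandwich variance by subject.
    """

    gamma1: float
    gamma2: float
    beta0: float
    beta1: float
    baseline_cumhaz: StepFunction
    config: LandmarkConfig
    cox_fit: CoxFit
    robust_covariance: Optional[pd.DataFrame] = None

    def linear_predictor(self, s, x) -> np.ndarray:
        st = np.asarray(s, dtype=float) / self.config.tau
        return self.gamma1 * st + self.gamma2 * st**2 + (self.beta0 + self.beta1 * st) * np.asarray(x)


def _cluster_robust_covariance(fit: CoxFit, stack: pd.DataFrame) -> pd.DataFrame:
    """Sandwich variance with score residuals summed within subject
    (subjects contribute many stacked records, so model-based standard
    errors are anti-conservative)."""
    from .coxph import _PartialLikelihood

    X = stack[_BASIS_COLS].to_numpy(dtype=float)
    time = stack["exit"].to_numpy(dtype=float)
    status = stack["status_w"].to_numpy(dtype=int)
    entry = stack["entry"].to_numpy(dtype=float)
    n, p = X.shape
    pl = _PartialLikelihood(X, time, status, entry, np.ones(n))
    beta = fit.coefficients.to_numpy()
    eta = X @ beta
    r = np.exp(eta)
    S0, S1, _ = pl._risk_sums(r, True, False)
    mean_at = S1 / S0[:, None]  # risk-set mean covariate per event time

    # per-record score residual: status * (x_i - xbar(t_i)) -
    #   exp(eta_i) * sum_{t_k in (entry_i, exit_i]} d_k/S0_k * (x_i - xbar(t_k))
    resid = np.zeros((n, p))
    ev_times = pl.event_times
    a = np.concatenate([[0.0], np.cumsum(pl.dsum / S0)])
    axbar = np.vstack([np.zeros(p), np.cumsum((pl.dsum / S0)[:, None] * mean_at, axis=0)])
    hi = np.searchsorted(ev_times, time, side="right")
    lo = np.searchsorted(ev_times, entry, side="right")
    A = a[hi] - a[lo]
    Axbar = axbar[hi] - axbar[lo]
    xbar_at_exit = np.zeros((n, p))
    is_event = status == 1
    pos = np.searchsorted(ev_times, time[is_event])
    xbar_at_exit[is_event] = mean_at[pos]
    resid = is_event[:, None] * (X - xbar_at_exit) - r[:, None] * (A[:, None] * X - Axbar)

    groups = stack["subject_id"].to_numpy()
    df = pd.DataFrame(resid).groupby(groups).sum()
    U = df.to_numpy()
    I_inv = fit.covariance.to_numpy()
    V = I_inv @ (U.T @ U) @ I_inv
    return pd.DataFrame(V, index=fit.names, columns=fit.names)


def fit_supermodel_ipl_star(
    stack: pd.DataFrame, config: Optional[LandmarkConfig] = None, robust_se: bool = True
) -> SupermodelFit:
    """Fit the pooled (ipl*) landmark supermodel.

    A single delayed-entry Cox fit on the stacked records with covariates
    (s/tau, (s/tau)^2, x, x * s/tau) and risk sets pooled across landmarks
    under one common baseline hazard.  Optionally attaches the
    cluster-sandwich covariance by subject.
    """
    config = config or LandmarkConfig()
    config.validate()
    if len(stack) == 0:
        raise EmptyInputError("empty landmark stack")
    if int(stack["status_w"].sum()) < 10:
        raise DomainError("landmark stack has fewer than 10 events")
    X = stack[_BASIS_COLS]
    fit = fit_cox(
        X,
        stack["exit"].to_numpy(dtype=float),
        stack["status_w"].to_numpy(dtype=int),
        entry=stack["entry"].to_numpy(dtype=float),
    )
    robust = _cluster_robust_covariance(fit, stack) if robust_se else None
    c = fit.coefficients
    return SupermodelFit(
        gamma1=float(c["s_tau"]),
        gamma2=float(c["s_tau_sq"]),
        beta0=float(c["x"]),
        beta1=float(c["x_s_tau"]),
        baseline_cumhaz=fit.baseline_cumhaz,
        config=config,
        cox_fit=fit,
        robust_covariance=robust,
    )


def evaluate_effect(fit: SupermodelFit, s: float) -> tuple[float, float]:
    """(landmark baseline term, index coefficient) at landmark s:
    gamma1 s/tau + gamma2 (s/tau)^2 and beta0 + beta1 s/tau."""
    if not 0 <= s <= fit.config.tau:
        raise DomainError(f"landmark s={s} outside [0, tau={fit.config.tau}]")
    st = s / fit.config.tau
    return fit.gamma1 * st + fit.gamma2 * st**2, fit.beta0 + fit.beta1 * st


def _H0_with_carry_forward(fit: SupermodelFit, t: np.ndarray) -> np.ndarray:
    """Baseline cumulative hazard, extended beyond the last event time by
    constant-hazard carry-forward (average hazard of the fitted range)."""
    H = fit.baseline_cumhaz
    t = np.asarray(t, dtype=float)
    last = H.final_knot
    out = np.asarray(H(t), dtype=float)
    beyond = t > last
    if np.any(beyond) and np.isfinite(last) and last > 0:
        warnings.warn(
            "baseline hazard extrapolated beyond the last event time "
            f"({last:.3g}); holding the average hazard constant",
            stacklevel=2,
        )
        rate = H.final_value / last
        out = np.where(beyond, H.final_value + rate * (t - last), out)
    return out


def dynamic_window_mortality(fit: SupermodelFit, x, s) -> np.ndarray:
    """Fixed-width conditional mortality
    F_w(s | x) = 1 - exp(-[H0(s+w) - H0(s)] exp(lp(s, x))), in [0, 1]."""
    s_arr = np.asarray(s, dtype=float)
    grid = np.asarray(fit.config.s_grid, dtype=float)
    if np.any(s_arr < grid[0]) or np.any(s_arr > grid[-1]):
        raise DomainError(f"landmark s outside the fitted grid [{grid[0]}, {grid[-1]}]")
    dH = _H0_with_carry_forward(fit, s_arr + fit.config.w) - _H0_with_carry_forward(fit, s_arr)
    lp = fit.linear_predictor(s_arr, x)
    out = 1.0 - np.exp(-np.maximum(dH, 0.0) * np.exp(lp))
    return out if out.ndim else float(out)


def mortality_curves(fit: SupermodelFit, profiles: pd.DataFrame) -> pd.DataFrame:
    """Fixed-width mortality over the landmark grid for each profile.

    ``profiles`` is indexed by label with a ``cvpi_comb`` column (as
    produced by :func:`dynapred.stacking.representative_profiles`).
    Returns a tidy frame (profile, s, mortality), one plottable series per
    profile.
    """
    grid = np.asarray(fit.config.s_grid, dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for label, row in profiles.iterrows():
            m = dynamic_window_mortality(fit, float(row["cvpi_comb"]), grid)
            rows.append(pd.DataFrame({"profile": label, "s": grid, "mortality": m}))
    return pd.concat(rows, ignore_index=True)


class LandmarkSupermodel(BaseEstimator):
    """Landmark dynamic-prediction supermodel, scikit-learn style.

    ``X`` is the per-subject combined prognostic index (one column);
    ``y`` a structured survival outcome.  ``fit`` builds the super
    prediction dataset over the landmark grid and fits the pooled
    delayed-entry Cox supermodel; ``predict_window_mortality(x, s)``
    returns fixed-width conditional mortalities.
    """

    def __init__(self, s_max: float = 7.0, s_step: float = 0.1, w: float = 5.0,
                 tau: Optional[float] = None, robust_se: bool = False):
        self.s_max = s_max
        self.s_step = s_step
        self.w = w
        self.tau = tau
        self.robust_se = robust_se

    def _config(self) -> LandmarkConfig:
        grid = np.round(np.arange(0.0, self.s_max + 1e-9, self.s_step), 10)
        return LandmarkConfig(s_grid=grid, w=self.w, tau=self.tau if self.tau is not None else self.s_max)

    def fit(self, X, y):
        time, status = unpack_survival(y)
        x = np.asarray(X, dtype=float).reshape(len(time), -1)
        if x.shape[1] != 1:
            raise DomainError("LandmarkSupermodel expects a single index column")
        ids = X.index if isinstance(X, (pd.DataFrame, pd.Series)) else pd.RangeIndex(len(time))
        data = pd.DataFrame({"time": time, "status": status}, index=ids)
        ds = SurvivalDataset(data)
        cvpi = pd.Series(x[:, 0], index=ids)
        config = self._config()
        self.stack_ = build_landmark_stack(ds, cvpi, config)
        self.fit_ = fit_supermodel_ipl_star(self.stack_, config, robust_se=self.robust_se)
        self.coef_ = self.fit_.cox_fit.coefficients.to_numpy()
        return self

    def predict_window_mortality(self, x, s) -> np.ndarray:
        return dynamic_window_mortality(self.fit_, x, s)

    def predict(self, X) -> np.ndarray:
        """Window mortality from baseline (s = 0) per subject."""
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray([dynamic_window_mortality(self.fit_, xi, 0.0) for xi in x])
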