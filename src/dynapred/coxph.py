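"""Cox proportional-hazards estimation with delayed entry.

The engine maximizes the Breslow-ties partial likelihood over risk sets

    R(t) = { j : entry_j < t <= time_j },

so left-truncated records (as produced by landmark stacking, where a
subject enters each landmark dataset at the landmark time) are handled
natively.  Risk-set sums are computed with suffix cumulative sums over the
exit- and entry-sorted records, giving O((n + E) p^2) cost per Newton
iteration.  The Breslow baseline cumulative hazard

    H0(t) = sum_{event times t_k <= t} d_k / sum_{R(t_k)} w_j exp(eta_j)

is retained on every fit so absolute risks can be predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._stepfun import StepFunction
from .datasets import unpack_survival
from .exceptions import DomainError, EstimationError

__all__ = ["CoxFit", "CoxPH", "fit_cox", "breslow_baseline", "model_chi_square", "cox_partial_loglik"]

# |beta_j| * sd(x_j) beyond this is treated as monotone likelihood (separation)
_SEPARATION_BOUND = 36.0


def _prepare_inputs(X, time, status, entry, weights):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(time).shape[0] != 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n = time.shape[0]
    if X.size == 0:
        X = np.empty((n, 0))
    if X.shape[0] != n or status.shape[0] != n:
        raise DomainError("X, time and status must agree in length")
    entry = np.zeros(n) if entry is None else np.asarray(entry, dtype=float)
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if entry.shape[0] != n or weights.shape[0] != n:
        raise DomainError("entry and weights must agree in length with time")
    if np.any(entry >= time):
        raise DomainError("every record requires entry < time")
    if np.any(weights < 0):
        raise DomainError("weights must be non-negative")
    if status.sum() < 1:
        raise EstimationError("no events in the data; the partial likelihood is flat")
    return X, time, status, entry, weights


class _PartialLikelihood:
    """Breslow partial log-likelihood with gradient and observed information.

    Precomputes sort orders and event-time groupings once; each call to
    :meth:`derivs` re-evaluates at a new coefficient vector.
    """

    def __init__(self, X, time, status, entry, weights):
        self.X, self.time, self.status, self.entry, self.w = X, time, status, entry, weights
        self.n, self.p = X.shape
        ev = status == 1
        self.event_times, inverse = np.unique(time[ev], return_inverse=True)
        k = self.event_times.size
        # per-event-time sums of weights and weighted covariates among events
        self.dsum = np.bincount(inverse, weights=weights[ev], minlength=k)
        self.xsum = np.zeros((k, self.p))
        for j in range(self.p):
            self.xsum[:, j] = np.bincount(inverse, weights=weights[ev] * X[ev, j], minlength=k)
        self.w_eta_events_idx = np.flatnonzero(ev)
        self.exit_order = np.argsort(time, kind="stable")
        self.sorted_exit = time[self.exit_order]
        self.entry_order = np.argsort(entry, kind="stable")
        self.sorted_entry = entry[self.entry_order]
        # positions: records with exit >= t_k  /  entry >= t_k
        self.pos_exit = np.searchsorted(self.sorted_exit, self.event_times, side="left")
        self.pos_entry = np.searchsorted(self.sorted_entry, self.event_times, side="left")

    @staticmethod
    def _suffix(arr):
        """suffix[i] = sum(arr[i:]) with suffix[n] = 0, along axis 0."""
        out = np.zeros((arr.shape[0] + 1,) + arr.shape[1:])
        out[:-1] = np.cumsum(arr[::-1], axis=0)[::-1]
        return out

    def _risk_sums(self, r, need_grad, need_info):
        """S0, S1, S2 over risk sets at each event time, via suffix sums."""
        X = self.X
        rx = r[:, None] * X if need_grad else None
        s0_e = self._suffix(r[self.exit_order])
        s0_s = self._suffix(r[self.entry_order])
        S0 = s0_e[self.pos_exit] - s0_s[self.pos_entry]
        S1 = S2 = None
        if need_grad:
            s1_e = self._suffix(rx[self.exit_order])
            s1_s = self._suffix(rx[self.entry_order])
            S1 = s1_e[self.pos_exit] - s1_s[self.pos_entry]
        if need_info:
            rxx = rx[:, :, None] * X[:, None, :]
            s2_e = self._suffix(rxx[self.exit_order])
            s2_s = self._suffix(rxx[self.entry_order])
            S2 = s2_e[self.pos_exit] - s2_s[self.pos_entry]
        return S0, S1, S2

    def loglik(self, beta):
        eta = self.X @ beta
        r = self.w * np.exp(eta)
        S0, _, _ = self._risk_sums(r, False, False)
        ev = self.w_eta_events_idx
        return float(np.sum(self.w[ev] * eta[ev]) - np.sum(self.dsum * np.log(S0)))

    def derivs(self, beta):
        eta = self.X @ beta
        r = self.w * np.exp(eta)
        S0, S1, S2 = self._risk_sums(r, True, True)
        ev = self.w_eta_events_idx
        ll = float(np.sum(self.w[ev] * eta[ev]) - np.sum(self.dsum * np.log(S0)))
        mean = S1 / S0[:, None]
        grad = self.xsum.sum(axis=0) - (self.dsum[:, None] * mean).sum(axis=0)
        info = np.einsum("k,kij->ij", self.dsum, S2 / S0[:, None, None]) - np.einsum(
            "k,ki,kj->ij", self.dsum, mean, mean
        )
        return ll, grad, info

    def eta_derivatives(self, beta):
        """Per-record score u_i = d pl / d eta_i and diagonal curvature
        h_i = -d^2 pl / d eta_i^2 (diagonal Hessian approximation), used by
        the penalized coordinate-descent solver."""
        eta = self.X @ beta
        r = self.w * np.exp(eta)
        S0, _, _ = self._risk_sums(r, False, False)
        # prefix sums over event times of d_k/S0_k and d_k/S0_k^2
        a = np.concatenate([[0.0], np.cumsum(self.dsum / S0)])
        b = np.concatenate([[0.0], np.cumsum(self.dsum / S0**2)])
        hi = np.searchsorted(self.event_times, self.time, side="right")
        lo = np.searchsorted(self.event_times, self.entry, side="right")
        A = a[hi] - a[lo]
        B = b[hi] - b[lo]
        u = self.w * self.status - r * A
        h = r * A - r**2 * B
        return u, np.maximum(h, 1e-12), eta

    def breslow_increments(self, beta):
        r = self.w * np.exp(self.X @ beta)
        S0, _, _ = self._risk_sums(r, False, False)
        return self.event_times, self.dsum / S0


@dataclass
class CoxFit:
    """A fitted Cox model: named log-hazard ratios, covariance, the null and
    full partial log-likelihoods, and the Breslow baseline cumulative hazard.

    ``exp(coefficients)`` are the hazard ratios.  ``entry_supported`` records
    that risk sets honoured delayed entry (always true for this engine)."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik_null: float
    loglik_full: float
    baseline_cumhaz: StepFunction
    n: int
    n_events: int
    ties_method: str = "breslow"
    entry_supported: bool = True

    @property
    def names(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("HR")

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())), index=self.coefficients.index)

    def wald_p_values(self) -> pd.Series:
        se = self.standard_errors
        z = self.coefficients / se.replace(0.0, np.nan)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coefficients.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_full + 2.0 * len(self.coefficients)

    def linear_predictor(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients.to_numpy()

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t|x) = exp(-H0(t) exp(x beta)); rows subjects, columns times."""
        lp = self.linear_predictor(X)
        H = np.atleast_1d(self.baseline_cumhaz(np.asarray(times, dtype=float)))
        return np.exp(-np.outer(np.exp(lp), H))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "se": self.standard_errors,
                "p": self.wald_p_values(),
            }
        )


def _column_names(X, p):
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{j}" for j in range(p)]


def fit_cox(
    X,
    time,
    status,
    entry=None,
    weights=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Breslow-ties Cox partial likelihood by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) covariate matrix (DataFrame columns become coefficient names);
        p = 0 fits the null model (Nelson-Aalen baseline).
    time, status : exit times (years) and 0/1 event indicators.
    entry : optional delayed-entry (left-truncation) times; default 0.
    weights : optional non-negative case weights.
    tol : convergence when the gradient max-norm falls below this.

    Raises
    ------
    EstimationError
        On monotone likelihood (separation, named covariate) or
        non-convergence within ``max_iter`` iterations.
    """
    Xv, time, status, entry, weights = _prepare_inputs(
        X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X, time, status, entry, weights
    )
    n, p = Xv.shape
    names = _column_names(X, p)
    if p:
        sd = Xv.std(axis=0)
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise EstimationError(f"constant covariate column: {names[const[0]]}")
    else:
        sd = np.empty(0)

    pl = _PartialLikelihood(Xv, time, status, entry, weights)
    beta = np.zeros(p)
    ll_null = pl.loglik(beta)
    ll = ll_null
    converged = p == 0
    for _ in range(max_iter):
        if converged:
            break
        ll, grad, info = pl.derivs(beta)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix: {exc}") from exc
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            if pl.loglik(cand) >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        bad = np.flatnonzero(np.abs(beta) * sd > _SEPARATION_BOUND)
        if bad.size:
            raise EstimationError(
                f"monotone partial likelihood (separation) on covariate: {names[bad[0]]}"
            )
    if not converged:
        _, grad, _ = pl.derivs(beta)
        if np.max(np.abs(grad)) >= tol:
            raise EstimationError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(gradient max-norm {np.max(np.abs(grad)):.3g})"
            )

    if p:
        ll, _, info = pl.derivs(beta)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information at optimum: {exc}") from exc
    else:
        cov = np.empty((0, 0))
        ll = ll_null

    knots, incr = pl.breslow_increments(beta)
    H0 = StepFunction(knots, np.cumsum(incr)) if knots.size else StepFunction(np.empty(0), np.empty(0))
    return CoxFit(
        coefficients=pd.Series(beta, index=names, name="coef"),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik_null=ll_null,
        loglik_full=ll,
        baseline_cumhaz=H0,
        n=n,
        n_events=int(status.sum()),
    )


def breslow_baseline(fit: CoxFit, X, time, status, entry=None, weights=None) -> StepFunction:
    """Recompute the Breslow baseline cumulative hazard of ``fit`` on data.

    H0(t) = sum over event times t_k <= t of d_k / sum_{R(t_k)} w_j exp(eta_j),
    honouring entry times.  With all coefficients zero this reduces to the
    Nelson-Aalen estimator exactly.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X
    Xv, time, status, entry, weights = _prepare_inputs(Xv, time, status, entry, weights)
    pl = _PartialLikelihood(Xv, time, status, entry, weights)
    beta = fit.coefficients.to_numpy() if len(fit.coefficients) else np.zeros(Xv.shape[1])
    knots, incr = pl.breslow_increments(beta)
    return StepFunction(knots, np.cumsum(incr))


def model_chi_square(fit: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio model chi-square: 2 (ll_full - ll_null), df = #coefficients."""
    stat = max(2.0 * (fit.loglik_full - fit.loglik_null), 0.0)
    df = len(fit.coefficients)
    p = float(stats.chi2.sf(stat, df)) if df else 1.0
    return stat, df, p


def cox_partial_loglik(beta, X, time, status, entry=None, weights=None) -> float:
    """Breslow partial log-likelihood at an arbitrary coefficient vector
    (used for cross-validated deviance and by test oracles)."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X
    Xv, time, status, entry, weights = _prepare_inputs(Xv, time, status, entry, weights)
    pl = _PartialLikelihood(Xv, time, status, entry, weights)
    return pl.loglik(np.asarray(beta, dtype=float))


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model, scikit-learn style.

    ``y`` is a structured outcome array (see :func:`dynapred.datasets.
    as_survival`); delayed entry and case weights are passed to ``fit``.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray of log-hazard ratios
    feature_names_in_ : coefficient names
    covariance_ : inverse observed information
    baseline_cumhaz_ : Breslow H0 step function
    fit_ : the underlying :class:`CoxFit`
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, entry=None, sample_weight=None):
        time, status = unpack_survival(y)
        self.fit_ = fit_cox(X, time, status, entry=entry, weights=sample_weight,
                            tol=self.tol, max_iter=self.max_iter)
        self.coef_ = self.fit_.coefficients.to_numpy()
        self.feature_names_in_ = np.asarray(self.fit_.names, dtype=object)
        self.covariance_ = self.fit_.covariance.to_numpy()
        self.baseline_cumhaz_ = self.fit_.baseline_cumhaz
        self.loglik_ = self.fit_.loglik_full
        self.loglik_null_ = self.fit_.loglik_null
        return self

    def predict(self, X) -> np.ndarray:
        """Prognostic index (linear predictor) per subject."""
        return self.fit_.linear_predictor(X)

    def predict_cumulative_hazard(self, X, times) -> np.ndarray:
        lp = self.predict(X)
        H = np.atleast_1d(self.baseline_cumhaz_(np.asarray(times, dtype=float)))
        return np.outer(np.exp(lp), H)

    def predict_survival_function(self, X, times) -> np.ndarray:
        return np.exp(-self.predict_cumulative_hazard(X, times))

    def score(self, X, y) -> float:
        """Harrell's concordance of the prognostic index on (X, y)."""
        from .evaluation import concordance_index

        time, status = unpack_survival(y)
        return concordance_index(self.predict(X), time, status)
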