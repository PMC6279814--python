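"""Kaplan-Meier estimation and the log-rank test.

Tied times follow the events-before-censorings convention: subjects
censored at t are still in the risk set for events at t.  The log-rank
statistic uses the hypergeometric (ties-corrected) variance and a
chi-square reference with k - 1 degrees of freedom for k groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stepfun import StepFunction
from .exceptions import DomainError, EmptyInputError

__all__ = ["KMCurve", "km_estimate", "logrank_test"]


@dataclass
class KMCurve:
    """Product-limit survivor estimate.

    ``survival[i]`` is S(t) for t in [event_times[i], event_times[i+1]);
    S = 1 before the first distinct observed time.  ``at_risk`` and
    ``n_events`` count subjects at risk and events at each distinct time
    (censoring-only times are retained with n_events = 0 so the at-risk
    trajectory is complete).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def as_stepfunction(self) -> StepFunction:
        return StepFunction(self.event_times, self.survival, init=1.0)

    def __call__(self, t):
        return self.as_stepfunction()(t)

    def left_limit(self, t):
        return self.as_stepfunction().left_limit(t)


def km_estimate(time, status, weights=None) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_k <= t} (1 - d_k / n_k)."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if time.size == 0:
        raise EmptyInputError("km_estimate requires at least one subject")
    if np.any(time <= 0):
        raise DomainError("times must be strictly positive")
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)

    uniq, inverse = np.unique(time, return_inverse=True)
    d = np.bincount(inverse, weights=w * status, minlength=uniq.size)
    removed = np.bincount(inverse, weights=w, minlength=uniq.size)
    total = w.sum()
    at_risk = total - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    with np.errstate(invalid="ignore"):
        frac = np.where(at_risk > 0, 1.0 - d / at_risk, 1.0)
    survival = np.cumprod(frac)
    return KMCurve(event_times=uniq, survival=survival, at_risk=at_risk, n_events=d)


def logrank_test(time, status, group) -> tuple[float, float]:
    """k-sample log-rank (O - E) chi-square test.

    At each distinct event time t with d events out of n at risk, group g
    (n_g at risk, d_g events) contributes observed d_g and expected
    d n_g / n; the variance is hypergeometric with the ties correction
    (n - d)/(n - 1).  Returns (statistic, p) with p from the chi-square
    upper tail on k - 1 degrees of freedom.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    group = np.asarray(group)
    levels, gidx = np.unique(group, return_inverse=True)
    k = levels.size
    if k < 2:
        raise DomainError("logrank_test requires at least two non-empty groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):  # unreachable via np.unique; guards explicit level lists upstream
        raise DomainError("every group must contain at least one subject")

    uniq, inverse = np.unique(time, return_inverse=True)
    m = uniq.size
    # removed (any cause) and events per (time, group)
    rem = np.zeros((m, k))
    ev = np.zeros((m, k))
    np.add.at(rem, (inverse, gidx), 1.0)
    np.add.at(ev, (inverse, gidx), status.astype(float))
    at_risk_g = counts - np.vstack([np.zeros(k), np.cumsum(rem, axis=0)[:-1]])
    n_t = at_risk_g.sum(axis=1)
    d_t = ev.sum(axis=1)

    use = (d_t > 0) & (n_t > 1)
    O = ev[use].sum(axis=0)
    E = (d_t[use, None] * at_risk_g[use] / n_t[use, None]).sum(axis=0)
    # covariance of the group event counts, summed over event times
    V = np.zeros((k, k))
    for n, d, ng in zip(n_t[use], d_t[use], at_risk_g[use]):
        p = ng / n
        V += d * (n - d) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if diff.size == 0 or not np.any(np.abs(diff) > 0):
        return 0.0, 1.0
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return stat, p
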