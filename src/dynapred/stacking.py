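"""Cross-validated prognostic indices and the two-source stacked model.

A prognostic index (PI) is the linear predictor of a Cox model at a
subject's covariates.  Evaluating each subject under a model fitted
*without* that subject (leave-one-out) gives an honest, cross-validated
prognostic index (CVPI).  The clinical CVPI and the genetic CVPI are then
stacked: a two-covariate Cox fit

    h(t | CVPI) = h0(t) exp(alpha_clin * CVPI_clin + alpha_gene * CVPI_gene)

whose coefficients weight the two information sources, and whose linear
predictor defines the combined index CVPI_comb used for dynamic
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coxph import CoxFit, fit_cox
from .datasets import unpack_survival
from .exceptions import DomainError, EstimationError

__all__ = [
    "CVPIVector",
    "SuperLearnerFit",
    "loocv_prognostic_index",
    "fit_super_learner",
    "representative_profiles",
    "SuperLearner",
]

logger = logging.getLogger(__name__)


@dataclass
class CVPIVector:
    """Per-subject cross-validated prognostic index, centered to mean 0.

    ``source`` labels the information source ('clinical', 'genetic' or
    'combined').  Subjects whose leave-one-out fit failed carry NaN.
    """

    values: pd.Series  # indexed by subject_id
    source: str

    def __post_init__(self):
        finite = self.values.dropna()
        if len(finite) and abs(float(finite.mean())) > 1e-8:
            raise DomainError("CVPI values must be centered to mean 0")

    @property
    def subject_id(self) -> pd.Index:
        return self.values.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source": self.source, "value": self.values})


@dataclass
class SuperLearnerFit:
    """The stacked two-source model: stacking coefficients alpha_clin and
    alpha_gene, the underlying two-covariate Cox fit (with its Breslow
    baseline), and the combined index CVPI_comb."""

    alpha_clin: float
    alpha_gene: float
    cox_fit: CoxFit
    cvpi_comb: CVPIVector

    def combine(self, cvpi_clin, cvpi_gene) -> np.ndarray:
        """alpha_clin * clin + alpha_gene * gene for arbitrary index values."""
        return self.alpha_clin * np.asarray(cvpi_clin) + self.alpha_gene * np.asarray(cvpi_gene)


def _center(v: pd.Series) -> pd.Series:
    return v - v.dropna().mean()


def loocv_prognostic_index(
    X,
    time,
    status,
    fitter: Optional[Callable] = None,
    subject_id=None,
    source: str = "clinical",
    max_failure_rate: float = 0.10,
) -> CVPIVector:
    """Leave-one-out cross-validated prognostic index.

    For each subject i the model is fitted on all other subjects and its
    linear predictor is evaluated at x_i; the resulting vector is centered
    to mean 0.  ``fitter(X, time, status) -> CoxFit`` defaults to the
    unpenalized Cox fit.  A per-subject fit failure records NaN (logged);
    more than ``max_failure_rate`` failures aborts.
    """
    if isinstance(X, pd.DataFrame):
        if subject_id is None:
            subject_id = X.index
        Xv = X.to_numpy(dtype=float)
        names = list(X.columns)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[0] == 1 and np.asarray(time).shape[0] != 1:
            Xv = Xv.T
        names = [f"x{j}" for j in range(Xv.shape[1])]
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n = time.shape[0]
    if subject_id is None:
        subject_id = pd.RangeIndex(n)
    if status.sum() < 3:
        raise DomainError("leave-one-out CVPI needs at least 3 events")
    if fitter is None:
        fitter = fit_cox

    values = np.full(n, np.nan)
    failures = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            fit = fitter(pd.DataFrame(Xv[mask], columns=names), time[mask], status[mask])
            values[i] = float(fit.linear_predictor(Xv[i][None, :])[0])
        except EstimationError as exc:
            failures += 1
            logger.warning("loocv_prognostic_index: fold %s failed: %s", subject_id[i], exc)
        finally:
            mask[i] = True
    if failures > max_failure_rate * n:
        raise EstimationError(
            f"{failures}/{n} leave-one-out fits failed; model too unstable for CVPI"
        )
    series = _center(pd.Series(values, index=pd.Index(subject_id), name="cvpi"))
    return CVPIVector(series, source=source)


def fit_super_learner(cvpi_clin: CVPIVector, cvpi_gene: CVPIVector, time, status) -> SuperLearnerFit:
    """Stack the two cross-validated indices in a two-covariate Cox model.

    Subjects must coincide between the two vectors; pairs with a missing
    index are dropped.  Nearly collinear indices (|r| > 0.999) abort.
    """
    if not cvpi_clin.subject_id.equals(cvpi_gene.subject_id):
        raise DomainError("the two CVPI vectors must cover the same subjects in the same order")
    df = pd.DataFrame({"cvpi_clin": cvpi_clin.values, "cvpi_gene": cvpi_gene.values})
    ok = df.notna().all(axis=1).to_numpy()
    if (~ok).any():
        logger.info("fit_super_learner: dropping %d subjects with missing CVPI", int((~ok).sum()))
    time = np.asarray(time, dtype=float)[ok]
    status = np.asarray(status, dtype=int)[ok]
    sub = df.loc[ok]
    r = np.corrcoef(sub["cvpi_clin"], sub["cvpi_gene"])[0, 1]
    if abs(r) > 0.999:
        raise EstimationError(f"collinear prognostic indices (correlation {r:.4f})")
    fit = fit_cox(sub, time, status)
    a1 = float(fit.coefficients["cvpi_clin"])
    a2 = float(fit.coefficients["cvpi_gene"])
    comb_raw = a1 * df["cvpi_clin"] + a2 * df["cvpi_gene"]
    comb = CVPIVector(_center(comb_raw.rename("cvpi")), source="combined")
    return SuperLearnerFit(alpha_clin=a1, alpha_gene=a2, cox_fit=fit, cvpi_comb=comb)


def representative_profiles(
    cvpi_clin: CVPIVector, cvpi_gene: CVPIVector, sl: SuperLearnerFit
) -> pd.DataFrame:
    """Four quartile-based risk profiles.

    The upper and lower quartiles of each index define high/low risk
    nodes; the four (clinical, genetic) combinations are labelled
    A (low, low), B (high, low), C (low, high), D (high, high), each with
    its combined index alpha_clin * q_clin + alpha_gene * q_gene.
    """
    clin = cvpi_clin.values.dropna().to_numpy()
    gene = cvpi_gene.values.dropna().to_numpy()
    if min(clin.size, gene.size) < 8:
        raise DomainError("need at least 8 subjects for stable quartiles")
    c_lo, c_hi = np.percentile(clin, [25, 75])
    g_lo, g_hi = np.percentile(gene, [25, 75])
    rows = {
        "A": (c_lo, g_lo),
        "B": (c_hi, g_lo),
        "C": (c_lo, g_hi),
        "D": (c_hi, g_hi),
    }
    out = pd.DataFrame(
        [(label, qc, qg, float(sl.combine(qc, qg))) for label, (qc, qg) in rows.items()],
        columns=["profile", "cvpi_clin", "cvpi_gene", "cvpi_comb"],
    ).set_index("profile")
    return out


class SuperLearner(BaseEstimator):
    """Two-source stacking model, scikit-learn style.

    ``X`` carries the two cross-validated prognostic indices as columns
    (clinical first, genetic second); ``y`` is a structured survival
    outcome.  After ``fit``, ``alpha_`` holds the stacking coefficients and
    ``predict`` returns the combined index.
    """

    def fit(self, X, y):
        time, status = unpack_survival(y)
        if isinstance(X, pd.DataFrame):
            clin = pd.Series(X.iloc[:, 0].to_numpy(), index=X.index)
            gene = pd.Series(X.iloc[:, 1].to_numpy(), index=X.index)
        else:
            X = np.asarray(X, dtype=float)
            clin = pd.Series(X[:, 0])
            gene = pd.Series(X[:, 1])
        v_clin = CVPIVector(_center(clin), source="clinical")
        v_gene = CVPIVector(_center(gene), source="genetic")
        self.fit_ = fit_super_learner(v_clin, v_gene, time, status)
        self.alpha_ = np.array([self.fit_.alpha_clin, self.fit_.alpha_gene])
        self.coef_ = self.alpha_
        return self

    def predict(self, X) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.fit_.combine(X[:, 0], X[:, 1])
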