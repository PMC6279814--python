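"""Model evaluation: discrimination, prediction error, comparison tables.

Discrimination is summarized by Harrell's concordance index of the
prognostic index.  Prediction error uses the Kullback-Leibler (log-loss)
score under inverse-probability-of-censoring weighting: at each grid time
t a subject observed beyond t contributes -log S_hat_i(t) with weight
1/G_hat(t), a subject with an event by t contributes -log(1 - S_hat_i(t))
with weight 1/G_hat(T_i-), and a subject censored by t contributes
nothing; G_hat is the Kaplan-Meier estimator of the censoring
distribution.  The covariate-free reference ("zero model") predicts the
pooled Kaplan-Meier curve for everyone, and the error-reduction curve is
1 - err_model / err_null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coxph import fit_cox, model_chi_square
from .datasets import SurvivalDataset
from .exceptions import DomainError, EmptyInputError
from .nonparametric import km_estimate

__all__ = [
    "PredictionErrorCurve",
    "ModelComparison",
    "concordance_index",
    "kl_prediction_error",
    "compare_models",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-6  # survival probabilities clipped to [_CLIP, 1 - _CLIP] before logs


@dataclass
class PredictionErrorCurve:
    """KL prediction error over a time grid, with the covariate-free
    reference and the relative error reduction 1 - err_model/err_null."""

    time_grid: np.ndarray
    err_model: np.ndarray
    err_null: np.ndarray

    @property
    def reduction(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.err_null > 0, 1.0 - self.err_model / self.err_null, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time_grid,
                "err_model": self.err_model,
                "err_null": self.err_null,
                "reduction": self.reduction,
            }
        )


def concordance_index(prognostic_index, time, status) -> float:
    """Harrell's C: among usable pairs (the shorter observed time is an
    event, times distinct), the fraction where the higher index has the
    shorter time; ties in the index count 1/2."""
    pi = np.asarray(prognostic_index, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n = time.shape[0]
    if n < 2 or status.sum() < 1:
        raise DomainError("concordance needs at least two subjects and one event")
    t_i, t_j = time[:, None], time[None, :]
    usable = (t_i < t_j) & (status[:, None] == 1)
    if not usable.any():
        raise DomainError("no usable pairs for concordance")
    higher = pi[:, None] > pi[None, :]
    tied = pi[:, None] == pi[None, :]
    concordant = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(concordant / usable.sum())


def _as_survival_matrix(predicted_survival, n, grid):
    if callable(predicted_survival):
        S = np.column_stack([np.broadcast_to(predicted_survival(t), (n,)) for t in grid])
    else:
        S = np.asarray(predicted_survival, dtype=float)
        if S.shape != (n, len(grid)):
            raise DomainError(
                f"predicted survival must be (n_subjects, n_times) = {(n, len(grid))}, got {S.shape}"
            )
    if np.any(S < -1e-9) or np.any(S > 1 + 1e-9):
        raise DomainError("predicted survival probabilities must lie in [0, 1]")
    return np.clip(S, _CLIP, 1.0 - _CLIP)


def kl_prediction_error(predicted_survival, time, status, time_grid) -> PredictionErrorCurve:
    """IPCW Kullback-Leibler (log-loss) prediction-error curve.

    ``predicted_survival`` is either an (n, len(time_grid)) matrix of
    survivor probabilities or a callable t -> per-subject probabilities.
    Grid times at which the censoring KM has no support (beyond the last
    observed time) are truncated with a warning.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n = time.shape[0]
    grid = np.asarray(time_grid, dtype=float)
    t_max = time.max()
    if np.any(grid > t_max):
        warnings.warn("time grid truncated at the last observed time", stacklevel=2)
        grid = grid[grid <= t_max]
    if grid.size == 0:
        raise DomainError("empty evaluation grid after truncation")

    S = _as_survival_matrix(predicted_survival, n, grid)
    G = km_estimate(time, 1 - status)  # censoring survivor function
    G_at_event = np.maximum(G.left_limit(time), _CLIP)

    km_pooled = km_estimate(time, status)
    S_null = np.clip(km_pooled(grid), _CLIP, 1.0 - _CLIP)

    err_model = np.empty(grid.size)
    err_null = np.empty(grid.size)
    for k, t in enumerate(grid):
        died = (time <= t) & (status == 1)
        alive = time > t
        w_alive = 1.0 / max(G(t), _CLIP)
        loss_m = np.zeros(n)
        loss_0 = np.zeros(n)
        loss_m[died] = -np.log(1.0 - S[died, k]) / G_at_event[died]
        loss_m[alive] = -np.log(S[alive, k]) * w_alive
        loss_0[died] = -np.log(1.0 - S_null[k]) / G_at_event[died]
        loss_0[alive] = -np.log(S_null[k]) * w_alive
        err_model[k] = loss_m.mean()
        err_null[k] = loss_0.mean()
    return PredictionErrorCurve(time_grid=grid, err_model=err_model, err_null=err_null)


@dataclass
class ModelComparison:
    """Per-model, per-stratum fit statistics (chi-square, df, concordance)."""

    table: pd.DataFrame  # columns: model, stratum, chi_square, df, p, concordance, n, n_events, small_sample

    def pivot(self, value: str = "chi_square") -> pd.DataFrame:
        return self.table.pivot(index="model", columns="stratum", values=value)


def compare_models(
    dataset: SurvivalDataset,
    model_covariates: dict[str, pd.DataFrame],
    split_variable: Optional[str] = None,
    min_events: int = 10,
) -> ModelComparison:
    """Refit each candidate model on the full cohort and within each level
    of ``split_variable``, reporting the likelihood-ratio chi-square and
    Harrell's concordance of the in-stratum prognostic index.

    ``model_covariates`` maps a model name to its covariate DataFrame
    (aligned with the dataset's subjects).  Strata with fewer than
    ``min_events`` events are reported but flagged.
    """
    strata: list[tuple[str, np.ndarray]] = [("full", np.ones(dataset.n_subjects, dtype=bool))]
    if split_variable is not None:
        col = dataset.clinical[split_variable]
        levels = pd.unique(col.dropna())
        if len(levels) < 2:
            raise DomainError(f"split variable {split_variable} has fewer than two levels")
        for lev in levels:
            mask = (col == lev).to_numpy()
            if mask.sum() == 0:
                raise EmptyInputError(f"split level {lev} selects zero subjects")
            strata.append((f"{split_variable}={lev}", mask))

    rows = []
    for name, X in model_covariates.items():
        if len(X) != dataset.n_subjects:
            raise DomainError(f"model {name}: covariates not aligned with dataset")
        for stratum, mask in strata:
            t, s = dataset.time[mask], dataset.status[mask]
            Xm = X.loc[mask] if isinstance(X, pd.DataFrame) else X[mask]
            n_ev = int(s.sum())
            fit = fit_cox(Xm, t, s)
            chi2, df, p = model_chi_square(fit)
            c = concordance_index(fit.linear_predictor(Xm), t, s)
            rows.append(
                {
                    "model": name,
                    "stratum": stratum,
                    "chi_square": chi2,
                    "df": df,
                    "p": p,
                    "concordance": c,
                    "n": int(mask.sum()),
                    "n_events": n_ev,
                    "small_sample": n_ev < min_events,
                }
            )
    return ModelComparison(pd.DataFrame(rows))
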