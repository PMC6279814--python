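"""Core data containers.

:class:`SurvivalDataset` is the universe every analysis stage consumes: one
row per subject with a right-censored survival time in years, an event
indicator, named clinical covariates and (optionally) a linked gene ×
subject expression matrix.  :class:`ExpressionMatrix` wraps the expression
block with its labels and a normalisation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, EmptyInputError, FormatError

RESERVED_COLUMNS = ("subject_id", "time", "status")


def as_survival(time, status) -> np.ndarray:
    """Pack (time, status) into a structured outcome array.

    Follows the scikit-survival convention: fields ``event`` (bool) and
    ``time`` (float), so the result composes with sklearn model selection
    as a single ``y``.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if time.shape != status.shape:
        raise DomainError("time and status must have equal length")
    y = np.empty(time.shape[0], dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = status.astype(bool)
    y["time"] = time
    return y


def unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, status) from any accepted outcome representation:
    a structured array with event/time fields, a (time, status) tuple,
    an (n, 2) array with columns (time, status), or a DataFrame with
    time/status columns."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(dtype=float), y["status"].to_numpy(dtype=int)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if not {"event", "time"} <= names:
            raise FormatError(f"structured outcome needs 'event' and 'time' fields, got {sorted(names)}")
        return y["time"].astype(float), y["event"].astype(int)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1], dtype=int)
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1].astype(int)
    raise FormatError("cannot interpret outcome y; use as_survival(time, status)")


class ExpressionMatrix:
    """Genes x samples expression values with unique labels.

    Raw values are non-negative; after :func:`dynapred.preprocessing.
    normalize_expression` values are on the log2(x+1) scale and the
    ``normalized`` flag is set.  The flag can only be toggled once.
    """

    def __init__(self, values: pd.DataFrame, normalized: bool = False):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        vals = values.astype(float)
        if not normalized and (vals.to_numpy() < 0).any():
            raise DomainError("raw expression values must be non-negative")
        self.values = vals
        self.normalized = bool(normalized)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.normalized)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.normalized)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.normalized == other.normalized and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        tag = "log-normalized" if self.normalized else "raw"
        return f"ExpressionMatrix({g} genes x {s} samples, {tag})"


@dataclass
class SurvivalDataset:
    """Per-subject survival outcomes, clinical covariates and optional
    linked expression.

    Parameters
    ----------
    data : DataFrame indexed by subject_id with columns ``time`` (years,
        strictly positive), ``status`` (0/1 event indicator) and any number
        of named clinical covariates.
    expression : optional ExpressionMatrix whose sample ids are a bijection
        with the subject ids.
    truth : optional record of generating parameters; present only for
        synthetic cohorts.
    """

    data: pd.DataFrame
    expression: Optional[ExpressionMatrix] = None
    truth: Optional[Any] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if "time" not in self.data.columns or "status" not in self.data.columns:
            raise FormatError("dataset requires 'time' and 'status' columns")
        if len(self.data) == 0:
            raise EmptyInputError("dataset has zero subjects")
        if self.data.index.duplicated().any():
            raise FormatError("subject ids must be unique")
        t = self.data["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise DomainError("survival times must be strictly positive and finite")
        s = self.data["status"].to_numpy()
        if not np.isin(s, (0, 1)).all():
            raise DomainError("status must be binary 0/1")
        if self.expression is not None:
            expr_ids = set(self.expression.sample_ids)
            subj_ids = set(self.data.index)
            if expr_ids != subj_ids:
                raise FormatError(
                    "expression samples must be a bijection with subject ids "
                    f"({len(subj_ids - expr_ids)} subjects lack expression, "
                    f"{len(expr_ids - subj_ids)} expression columns unmatched)"
                )

    @property
    def subject_id(self) -> pd.Index:
        return self.data.index

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.data["status"].to_numpy(dtype=int)

    @property
    def clinical(self) -> pd.DataFrame:
        """Covariate columns only (time/status stripped)."""
        drop = [c for c in ("time", "status") if c in self.data.columns]
        return self.data.drop(columns=drop)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.clinical.columns)

    def expression_aligned(self) -> pd.DataFrame:
        """Expression block reordered to subject order (genes x subjects)."""
        if self.expression is None:
            raise EmptyInputError("dataset carries no expression matrix")
        return self.expression.values.loc[:, self.data.index]

    def subset(self, subject_ids) -> "SurvivalDataset":
        ids = [i for i in subject_ids if i in self.data.index]
        if not ids:
            raise EmptyInputError("subset selects zero subjects")
        expr = self.expression.subset_samples(ids) if self.expression is not None else None
        return SurvivalDataset(self.data.loc[ids].copy(), expr, self.truth)

    def equals(self, other: "SurvivalDataset") -> bool:
        if not self.data.equals(other.data):
            return False
        if (self.expression is None) != (other.expression is None):
            return False
        if self.expression is not None and not self.expression.equals(other.expression):
            return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        expr = "" if self.expression is None else f", expression {self.expression.shape[0]} genes"
        return (
            f"SurvivalDataset({self.n_subjects} subjects, "
            f"{int(self.status.sum())} events, "
            f"{len(self.covariate_names)} covariates{expr})"
        )
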