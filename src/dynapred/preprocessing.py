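"""Input reading, validation, log-normalization and sample matching.

The two input tables are tab-separated text: a clinical table (one row per
subject: subject_id, time, status, then named covariates) and an
expression matrix (first column gene ids, remaining columns sample ids).
Expression values are log2(x + 1)-normalized before model fitting, and
genes are pre-filtered by the Wald p-value of a single-covariate Cox fit.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coxph import fit_cox
from .datasets import ExpressionMatrix, SurvivalDataset
from .exceptions import DomainError, EmptyInputError, EstimationError, FormatError

__all__ = [
    "read_clinical_table",
    "read_expression_matrix",
    "normalize_expression",
    "univariate_gene_screen",
    "match_samples",
]

logger = logging.getLogger(__name__)


def read_clinical_table(path, schema: Optional[dict] = None) -> SurvivalDataset:
    """Read a tab-separated clinical table into a :class:`SurvivalDataset`.

    The header must contain ``subject_id``, ``time`` and ``status``.  Rows
    with missing or non-positive time, or missing status, are dropped with a
    logged count.  ``schema`` may force covariates to ``continuous`` or
    ``categorical`` (otherwise numeric dtype decides).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in ("subject_id", "time", "status") if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing mandatory columns: {missing}")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["status"] = pd.to_numeric(df["status"], errors="coerce")
    ok = df["time"].notna() & (df["time"] > 0) & df["status"].isin([0, 1])
    if (~ok).any():
        logger.warning("read_clinical_table: dropped %d rows with invalid time/status", int((~ok).sum()))
    df = df.loc[ok]
    if len(df) == 0:
        raise EmptyInputError("clinical table has zero usable rows")
    df = df.set_index("subject_id")
    if schema:
        for name, kind in schema.items():
            if name in df.columns:
                df[name] = df[name].astype(float) if kind == "continuous" else df[name].astype(str)
    df["status"] = df["status"].astype(int)
    return SurvivalDataset(df)


def read_expression_matrix(path, normalized: bool = False) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix (first column gene ids).

    Duplicate gene or sample labels and ragged rows are format errors.
    ``normalized`` marks a file already on the log scale.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed expression file: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError("expression file has no sample columns")
    if df.isna().to_numpy().any():
        raise FormatError("expression file has missing or ragged entries")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, normalized=normalized)


def normalize_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1)-normalize a raw expression matrix (flag toggles once)."""
    if m.normalized:
        raise DomainError("expression matrix is already normalized")
    vals = m.values.to_numpy()
    if (vals < 0).any():
        raise DomainError("negative value in raw expression matrix")
    return ExpressionMatrix(pd.DataFrame(np.log2(vals + 1.0), index=m.gene_ids, columns=m.sample_ids),
                            normalized=True)


def univariate_gene_screen(
    m: ExpressionMatrix,
    dataset: SurvivalDataset,
    alpha: float = 0.05,
) -> list[str]:
    """Genes whose single-covariate Cox Wald p-value is below ``alpha``.

    Order is preserved from the input matrix.  Genes whose univariate fit
    fails (constant expression, separation) are dropped with a logged count.
    """
    if not 0 < alpha <= 1:
        raise DomainError("alpha must lie in (0, 1]")
    shared = [s for s in dataset.subject_id if s in set(m.sample_ids)]
    if not shared:
        raise EmptyInputError("no samples shared between expression matrix and dataset")
    sub = dataset.subset(shared)
    X = m.values.loc[:, shared].to_numpy()
    time, status = sub.time, sub.status
    kept, failed = [], 0
    for gid, row in zip(m.gene_ids, X):
        try:
            fit = fit_cox(row[:, None], time, status)
        except EstimationError:
            failed += 1
            continue
        if float(fit.wald_p_values().iloc[0]) < alpha:
            kept.append(gid)
    if failed:
        logger.warning("univariate_gene_screen: %d genes failed to fit and were dropped", failed)
    return kept


def match_samples(dataset: SurvivalDataset, m: ExpressionMatrix) -> SurvivalDataset:
    """Intersect clinical subjects with expression samples and attach the
    expression block, both re-ordered to the clinical order.  Drops are
    logged; an empty intersection is an error.  Idempotent."""
    shared = [s for s in dataset.subject_id if s in set(m.sample_ids)]
    if not shared:
        raise EmptyInputError("no subjects shared between clinical and expression data")
    n_drop_clin = dataset.n_subjects - len(shared)
    n_drop_expr = len(m.sample_ids) - len(shared)
    if n_drop_clin or n_drop_expr:
        logger.info("match_samples: dropped %d clinical subjects and %d expression samples",
                    n_drop_clin, n_drop_expr)
    return SurvivalDataset(dataset.data.loc[shared].copy(),
                           m.subset_samples(shared), dataset.truth)
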