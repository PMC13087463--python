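"""Covariate residualization and expression-level inclusion filtering."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


def _design_matrix(cov_values: np.ndarray) -> np.ndarray:
    """Samples x (1 + covariates) design with intercept prepended."""
    n = cov_values.shape[1]
    return np.column_stack([np.ones(n), cov_values.T])


def residualize(expr: ExpressionMatrix, cov: pd.DataFrame) -> ExpressionMatrix:
    """OLS-residualize each gene's expression on the covariate rows.

    The covariate table is covariates x samples; an intercept is added
    internally. Sample sets must match exactly (same order). Residuals are
    orthogonal to every covariate and to the intercept.
    """
    if list(cov.columns) != expr.sample_ids:
        raise ValueError("covariate samples must match expression samples exactly (same order)")
    X = _design_matrix(cov.to_numpy(float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_rows(X, cov.index.tolist())
        raise ValueError(f"rank-deficient covariates; collinear rows: {collinear}")
    Y = expr.values.to_numpy(float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(expr.anchors, out)


def _collinear_rows(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for covariate rows linearly dependent on earlier ones."""
    bad = []
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[j - 1])
        else:
            kept = cand
    return bad


def expression_filter(
    tpm: pd.DataFrame,
    counts: pd.DataFrame,
    tpm_floor: float = 0.1,
    count_floor: int = 6,
    frac: float = 0.20,
) -> pd.Series:
    """Gene inclusion mask from TPM and read-count tables.

    A gene is kept iff TPM > ``tpm_floor`` (strict) in at least ``frac`` of
    samples AND counts >= ``count_floor`` (inclusive) in at least ``frac``
    of samples.
    """
    if not tpm.index.equals(counts.index) or not tpm.columns.equals(counts.columns):
        raise ValueError("tpm and counts must share gene and sample indices")
    tpm_ok = (tpm > tpm_floor).mean(axis=1) >= frac
    count_ok = (counts >= count_floor).mean(axis=1) >= frac
    return tpm_ok & count_ok
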