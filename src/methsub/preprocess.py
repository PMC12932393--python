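"""Pre-clustering transformation of methylation matrices.

Residualizes each probe against covariates by ordinary least squares,
filters non-variant probes on a robust spread statistic (the per-probe 90th
percentile of absolute deviations from the probe median), and intersects
probe panels across array platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import logit
from .containers import BetaMatrix, ResidualMatrix


def _build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns: {bad}")
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    cols = ["intercept"] + list(X.columns)
    D = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in X.columns])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the collinear columns by QR pivoting
        _, R = np.linalg.qr(D)
        dep = [cols[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")
    return D, cols


def residualize(beta: BetaMatrix | pd.DataFrame,
                covariates: pd.DataFrame | None = None,
                use_m_values: bool = False) -> ResidualMatrix:
    """Per-probe OLS residuals of methylation on covariates.

    Parameters
    ----------
    beta
        Probes x samples methylation values.
    covariates
        Samples x covariates table aligned to the sample ids.  ``None`` or an
        empty frame fits an intercept-only model (per-probe centering).
    use_m_values
        Regress on logit-transformed betas (M-values) instead of betas.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    Y = values.to_numpy(dtype=float)
    if use_m_values:
        Y = logit(Y)
    if covariates is None or covariates.shape[1] == 0:
        D = np.ones((Y.shape[1], 1))
        cols = ["intercept"]
    else:
        cov = covariates.loc[list(values.columns)]
        D, cols = _build_design(cov)
    coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    resid = Y - (D @ coef).T
    return ResidualMatrix(
        values=pd.DataFrame(resid, index=values.index, columns=values.columns),
        design_columns=cols)


def spread_statistic(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-probe 90th percentile of |value - probe median| across samples."""
    X = np.asarray(values, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    return np.percentile(np.abs(X - med), 90, axis=1)


def filter_most_variable(residuals: ResidualMatrix,
                         spread_quantile: float = 0.5) -> ResidualMatrix:
    """Retain probes whose spread statistic exceeds a quantile cutoff.

    The cutoff is the ``spread_quantile`` quantile of the spread statistic's
    distribution across probes; probes strictly above it are retained.  At
    ``spread_quantile == 0`` every probe with positive spread is retained.
    """
    if not (0 <= spread_quantile < 1):
        raise ValueError("spread_quantile must lie in [0, 1)")
    if residuals.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to measure spread")
    stat = spread_statistic(residuals.values)
    cutoff = 0.0 if spread_quantile == 0 else float(np.quantile(stat, spread_quantile))
    keep = stat > cutoff
    return ResidualMatrix(values=residuals.values.loc[keep],
                          design_columns=list(residuals.design_columns))


def intersect_platform(residuals: ResidualMatrix,
                       probe_list) -> ResidualMatrix:
    """Restrict to probes present on another platform, preserving order."""
    probes = set(probe_list)
    if not probes:
        raise ValueError("probe list is empty")
    keep = residuals.values.index.isin(probes)
    if not keep.any():
        raise ValueError("no probes shared with the supplied platform list")
    return ResidualMatrix(values=residuals.values.loc[keep],
                          design_columns=list(residuals.design_columns))
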