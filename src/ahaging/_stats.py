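"""Shared statistical primitives.

Multi-response ordinary least squares with t-tests (one design matrix shared by
many protein responses, limma-style), Benjamini-Hochberg adjustment, and the
upper-tail hypergeometric probability used by every over-representation test in
the package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["OLSResult", "ols_tstats", "bh_adjust", "hypergeom_upper_tail"]


@dataclass(frozen=True)
class OLSResult:
    """Coefficients and inference for OLS of many responses on one design.

    All arrays are (n_coefficients, n_responses). ``estimable`` is False when
    the design matrix is rank deficient, in which case every statistic is NaN.
    """

    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray
    df: int
    estimable: bool


def ols_tstats(X: np.ndarray, Y: np.ndarray) -> OLSResult:
    """Fit ``Y ~ X`` by OLS for every column of ``Y`` simultaneously.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    Y : (n,) or (n, m) response matrix; each column is fit independently
        against the same design.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValidationError(f"design has {n} rows but responses have {Y.shape[0]}")
    if n <= p or np.linalg.matrix_rank(X) < p:
        nan = np.full((p, Y.shape[1]), np.nan)
        return OLSResult(nan, nan.copy(), nan.copy(), nan.copy(), max(n - p, 0), False)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    return OLSResult(beta, se, tstat, pval, df, True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(overlap: int, draw_size: int, n_success: int, n_total: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(n_total, n_success, draw_size)."""
    if not 0 <= n_success <= n_total:
        raise ValidationError("need 0 <= n_success <= n_total")
    if not 0 <= draw_size <= n_total:
        raise ValidationError("need 0 <= draw_size <= n_total")
    return float(sps.hypergeom.sf(overlap - 1, n_total, n_success, draw_size))
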