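"""Vectorized OLS primitives shared by the association modules.

The per-CpG scans use Frisch-Waugh-Lovell residualization: the outcome and
every candidate predictor are residualized on the covariate design once, then
each slope is a univariate regression of residuals. Estimates, standard
errors and t-based P-values are identical to the full-design OLS (asserted
against a normal-equations oracle in the test suite); degrees of freedom use
the full design size.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, stats


def design_matrix(covars, add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Covariate design with intercept; drops collinear columns with a warning."""
    if covars is None:
        C = np.empty((0, 0))
        names: list[str] = []
    else:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = list(covars.columns) if hasattr(covars, "columns") else \
            [f"c{i}" for i in range(C.shape[1])]
    if add_intercept:
        if C.shape[0] == 0:
            raise ValueError("cannot infer sample count from empty covariates")
        C = np.column_stack([np.ones(C.shape[0]), C])
        names = ["intercept"] + names
    # pivoted QR to detect collinear columns
    q, r, piv = linalg.qr(C, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(C.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < C.shape[1]:
        drop = sorted(piv[rank:])
        dropped = [names[j] for j in drop]
        warnings.warn(f"dropping collinear covariates: {dropped}", stacklevel=2)
        keep = sorted(piv[:rank])
        C = C[:, keep]
        names = [names[j] for j in keep]
    return C, names


def residualize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of A after OLS on design C."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != C.shape[0]:
        A = A.T
    coef, *_ = np.linalg.lstsq(C, A, rcond=None)
    return A - C @ coef


def slope_scan(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Per-column OLS slope of y on X[:, j] adjusting for design C.

    Returns (effect, se, p, df) arrays; columns of X that are constant after
    residualization yield NaN estimates.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    df = n - C.shape[1] - 1
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom (n={n}, covariates={C.shape[1]})")
    ry = residualize(y[:, None], C).ravel()
    rX = residualize(X, C)
    sxx = np.einsum("ij,ij->j", rX, rX)
    sxy = rX.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = ry @ ry - slope**2 * sxx
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sxx <= np.finfo(float).eps * n
    slope[degenerate] = np.nan
    se[degenerate] = np.nan
    p[degenerate] = np.nan
    return slope, se, p, df


def ols_fit(y: np.ndarray, X: np.ndarray):
    """Plain multiple regression: coefficients, SEs, two-sided t P-values, df."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("insufficient degrees of freedom")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - X @ coef
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef, se, p, df, resid
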