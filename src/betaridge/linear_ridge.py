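"""Ordinary least squares and Hoerl-Kennard ridge regression.

Ridge theory is stated on the correlation scale: predictors are centered and
scaled to unit column length so that ``S = Z'Z`` is the correlation matrix,
the response is centered, and the ridge estimator is

    beta_hat(k) = (S + k I)^{-1} Z'y = W(k) beta_hat_OLS .

The biasing constant can be fixed by the user or chosen by the
Hoerl-Kennard rule ``k = p sigma^2 / (beta' beta)`` evaluated at the OLS
quantities on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import Dataset, standardize_predictors

__all__ = [
    "LinearFit",
    "RidgeFit",
    "fit_ols",
    "ridge_estimate",
    "hoerl_kennard_k",
    "ridge_mse_canonical",
    "fit_ridge",
]


def _gaussian_llf(resid: np.ndarray) -> float:
    """Gaussian log-likelihood at the ML variance sigma2 = RSS / n."""
    n = resid.size
    rss = float(resid @ resid)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


@dataclass
class LinearFit:
    """OLS fit summary (intercept first in all coefficient vectors)."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    r_squared: float
    fvalue: float
    llf: float
    n: int
    k_params: int
    fittedvalues: np.ndarray
    resid: np.ndarray
    label: str = "OLS"


def fit_ols(dataset: Dataset) -> LinearFit:
    """Least squares via a QR-based solver with classical inference.

    ``k_params`` counts the p + 1 coefficients plus the residual variance,
    the convention used throughout the AIC/BIC comparisons.
    """
    if dataset.n < dataset.p + 2:
        raise ValueError("need n >= p + 2 observations to fit")
    exog = sm.add_constant(dataset.X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the dependent columns via near-zero R diagonal of a pivoted QR
        corr = np.corrcoef(dataset.X.to_numpy(dtype=float).T)
        dep = [
            dataset.column_names[i]
            for i in range(dataset.p)
            for j in range(i + 1, dataset.p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient (columns: {dep or 'unknown'})")
    res = sm.OLS(dataset.y, exog).fit()
    names = ["const"] + dataset.column_names
    return LinearFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        sigma2=float(res.mse_resid),
        r_squared=float(res.rsquared),
        fvalue=float(res.fvalue) if dataset.p > 0 else 0.0,
        llf=float(res.llf),
        n=dataset.n,
        k_params=dataset.p + 2,
        fittedvalues=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
    )


def ridge_estimate(X_std: np.ndarray, y_c: np.ndarray, k: float) -> np.ndarray:
    """Solve the ridge normal equations (S + kI) b = X'y on given inputs."""
    if k < 0:
        raise ValueError("ridge constant k must be >= 0")
    X_std = np.asarray(X_std, dtype=float)
    y_c = np.asarray(y_c, dtype=float).ravel()
    S = X_std.T @ X_std
    A = S + k * np.eye(S.shape[0])
    return np.linalg.solve(A, X_std.T @ y_c)


def hoerl_kennard_k(sigma2_hat: float, beta_hat: np.ndarray, p: int) -> float:
    """Hoerl-Kennard biasing parameter k = p sigma2 / (beta' beta)."""
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    bb = float(beta_hat @ beta_hat)
    if bb == 0.0:
        raise ValueError("coefficient vector is identically zero")
    if sigma2_hat < 0:
        raise ValueError("sigma2_hat must be non-negative")
    return p * float(sigma2_hat) / bb


def ridge_mse_canonical(lambdas, alphas, sigma2: float, k: float) -> float:
    """Ridge MSE in canonical coordinates.

    sum_i (lambda_i sigma^2 + k^2 alpha_i^2) / (lambda_i + k)^2 -- the
    variance-plus-squared-bias decomposition of E||beta_hat(k) - beta||^2.
    The bias numerator carries k^2 so that the large-k limit tends to the
    total squared signal sum alpha_i^2, as shrinkage to zero demands.
    """
    lambdas = np.asarray(lambdas, dtype=float).ravel()
    alphas = np.asarray(alphas, dtype=float).ravel()
    if np.any(lambdas <= 0):
        raise ValueError("all eigenvalues must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(
        np.sum((lambdas * sigma2 + k**2 * alphas**2) / (lambdas + k) ** 2)
    )


@dataclass
class RidgeFit:
    """Ridge fit on the standardized (SC) scale with raw back-transform."""

    k: float
    params_sc: pd.Series
    params: pd.Series  # raw scale incl. intercept
    bse_sc: pd.Series
    tvalues_sc: pd.Series
    pvalues: pd.Series
    S: np.ndarray
    eigenvalues: np.ndarray
    alphas: np.ndarray
    W: np.ndarray
    llf: float
    n: int
    k_params: int
    fittedvalues: np.ndarray
    resid: np.ndarray
    sigma2: float
    label: str = "Ridge"


def fit_ridge(dataset: Dataset, k_policy="hoerl_kennard") -> RidgeFit:
    """Ridge regression with a fixed or Hoerl-Kennard-chosen constant.

    Predictors are standardized to unit length, the response centered; raw
    scale coefficients (and an intercept) are recovered exactly from the
    centering/scaling vectors.  Standard errors use the sandwich form
    sigma2 (S+kI)^{-1} S (S+kI)^{-1} of the linear shrinkage estimator.
    """
    if dataset.n < dataset.p + 2:
        raise ValueError("need n >= p + 2 observations to fit")
    Z, center, scale = standardize_predictors(dataset.X)
    y = dataset.y
    ybar = float(y.mean())
    y_c = y - ybar
    n, p = Z.shape
    S = Z.T @ Z

    beta_ols = np.linalg.lstsq(Z, y_c, rcond=None)[0]
    resid_ols = y_c - Z @ beta_ols
    sigma2_ols = float(resid_ols @ resid_ols) / (n - p - 1)

    if isinstance(k_policy, str):
        if k_policy != "hoerl_kennard":
            raise ValueError(f"unknown k policy {k_policy!r}")
        k = hoerl_kennard_k(sigma2_ols, beta_ols, p)
    else:
        k = float(k_policy)
        if k < 0:
            raise ValueError("ridge constant k must be >= 0")

    beta_sc = ridge_estimate(Z, y_c, k)
    lam, Q = np.linalg.eigh(S)
    alphas = Q.T @ beta_ols
    Ainv = np.linalg.inv(S + k * np.eye(p))
    W = Ainv @ S

    beta_raw = beta_sc / scale
    intercept = ybar - float(beta_raw @ center)
    fitted = intercept + dataset.X.to_numpy(dtype=float) @ beta_raw
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = rss / (n - p - 1)
    cov_sc = sigma2 * (Ainv @ S @ Ainv)
    bse_sc = np.sqrt(np.diag(cov_sc))
    t_sc = beta_sc / bse_sc
    pvals = 2.0 * stats.t.sf(np.abs(t_sc), df=n - p - 1)

    names = dataset.column_names
    return RidgeFit(
        k=k,
        params_sc=pd.Series(beta_sc, index=names),
        params=pd.Series(
            np.concatenate([[intercept], beta_raw]), index=["const"] + names
        ),
        bse_sc=pd.Series(bse_sc, index=names),
        tvalues_sc=pd.Series(t_sc, index=names),
        pvalues=pd.Series(pvals, index=names),
        S=S,
        eigenvalues=lam,
        alphas=alphas,
        W=W,
        llf=_gaussian_llf(resid),
        n=n,
        k_params=p + 2,
        fittedvalues=fitted,
        resid=resid,
        sigma2=sigma2,
    )
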