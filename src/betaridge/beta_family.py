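"""Beta regression by maximum likelihood and its ridge-shrunk variant.

The response lives strictly inside (0, 1) and follows a beta law
parameterized by mean mu and precision phi (shapes mu*phi and (1-mu)*phi),
with logit-linked mean.  Multicollinearity inflates the variance of the ML
coefficients; the beta ridge estimator shrinks them through the Fisher
information of the mean submodel,

    beta_BRR(k) = (X'WX + kI)^{-1} X'WX beta_ML ,

the direct analogue of Hoerl-Kennard shrinkage in the weighted geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, expit, gammaln, logit, polygamma

from .data_io import Dataset

__all__ = [
    "BetaFit",
    "BetaRidgeFit",
    "beta_logpdf",
    "link_logit",
    "inv_link_logit",
    "fit_beta_ml",
    "working_weights",
    "fit_beta_ridge",
    "beta_deviance_residuals",
]


def beta_logpdf(y, mu, phi):
    """Log density of the mean/precision beta law at y.

    Shapes are a = mu*phi and b = (1-mu)*phi, so E(y) = mu and
    var(y) = mu(1-mu)/(1+phi).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def link_logit(mu):
    """Logit link eta = log(mu / (1 - mu))."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    return logit(mu)


def inv_link_logit(eta):
    """Inverse logit mu = 1 / (1 + exp(-eta))."""
    return expit(np.asarray(eta, dtype=float))


def _mu(X, beta):
    # clip linear-predictor overflow so intermediate optimizer steps stay
    # finite; converged fits are interior and unaffected
    return np.clip(expit(X @ beta), 1e-12, 1.0 - 1e-12)


def _loglik(beta, phi, X, y, logy, log1y):
    mu = _mu(X, beta)
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * logy
            + (b - 1.0) * log1y
        )
    )


def _score(beta, phi, X, y, ystar, logy, log1y):
    """Analytic gradient in (beta, phi)."""
    mu = _mu(X, beta)
    a = mu * phi
    b = (1.0 - mu) * phi
    mustar = digamma(a) - digamma(b)
    g_beta = X.T @ (phi * (ystar - mustar) * mu * (1.0 - mu))
    g_phi = float(
        np.sum(digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b)
               + mu * logy + (1.0 - mu) * log1y)
    )
    return g_beta, g_phi


@dataclass
class BetaFit:
    """Converged beta-regression ML fit (intercept first)."""

    params: pd.Series
    phi: float
    bse: pd.Series
    bse_phi: float
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    mu: np.ndarray
    eta: np.ndarray
    weights: np.ndarray
    y: np.ndarray
    X: np.ndarray = field(repr=False)
    n: int = 0
    k_params: int = 0
    converged: bool = True
    score_max: float = np.nan
    label: str = "Beta"

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.mu


class BetaConvergenceError(RuntimeError):
    """ML optimizer failed; carries the best trajectory seen."""

    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


def fit_beta_ml(dataset: Dataset, tol: float = 1e-6, maxiter: int = 500) -> BetaFit:
    """Maximize the beta log-likelihood jointly in (beta, phi).

    A quasi-Newton pass on (beta, log phi) with the analytic score is
    polished by Newton steps on (beta, phi) until the score's largest entry
    falls below ``tol``.  Initial values: OLS of logit(y) on X for beta and
    the method-of-moments precision mu(1-mu)/v - 1 for phi.  Standard errors
    come from the inverse observed information.
    """
    if dataset.family_hint != "unit_interval":
        raise ValueError("beta regression requires a unit_interval response")
    if dataset.n < dataset.p + 2:
        raise ValueError("need n >= p + 2 observations to fit")
    X = np.column_stack(
        [np.ones(dataset.n), dataset.X.to_numpy(dtype=float)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    y = dataset.y
    logy = np.log(y)
    log1y = np.log1p(-y)
    ystar = logy - log1y

    beta0 = np.linalg.lstsq(X, ystar, rcond=None)[0]
    mu0 = expit(X @ beta0)
    v = float(np.var(y - mu0))
    mbar = float(mu0.mean())
    phi0 = mbar * (1.0 - mbar) / v - 1.0 if v > 0 else 100.0
    phi0 = float(np.clip(phi0, 0.5, 1e7))

    def nll(theta):
        beta, phi = theta[:-1], np.exp(theta[-1])
        return -_loglik(beta, phi, X, y, logy, log1y)

    def nll_grad(theta):
        beta, phi = theta[:-1], np.exp(theta[-1])
        gb, gp = _score(beta, phi, X, y, ystar, logy, log1y)
        return -np.concatenate([gb, [gp * phi]])

    theta0 = np.concatenate([beta0, [np.log(phi0)]])
    res = optimize.minimize(
        nll, theta0, jac=nll_grad, method="L-BFGS-B",
        bounds=[(None, None)] * len(beta0) + [(-10.0, 25.0)],
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta, phi = res.x[:-1], float(np.exp(res.x[-1]))

    # Fisher-scoring polish in (beta, phi) until the raw score is tiny
    trajectory = [np.concatenate([beta, [phi]])]
    for _ in range(100):
        gb, gp = _score(beta, phi, X, y, ystar, logy, log1y)
        score = np.concatenate([gb, [gp]])
        if np.max(np.abs(score)) < tol:
            break
        K = _expected_information(beta, phi, X)
        try:
            step = np.linalg.solve(K, score)
        except np.linalg.LinAlgError:
            break
        ll_old = _loglik(beta, phi, X, y, logy, log1y)
        scale_step = 1.0
        for _ in range(40):
            beta_new = beta + scale_step * step[:-1]
            phi_new = phi + scale_step * step[-1]
            if phi_new > 0 and _loglik(beta_new, phi_new, X, y, logy, log1y) >= ll_old - 1e-10:
                break
            scale_step *= 0.5
        else:
            break
        beta, phi = beta_new, float(phi_new)
        trajectory.append(np.concatenate([beta, [phi]]))

    gb, gp = _score(beta, phi, X, y, ystar, logy, log1y)
    score = np.concatenate([gb, [gp]])
    score_max = float(np.max(np.abs(score)))
    # scale-invariant criterion: score measured in the information metric,
    # so convergence does not depend on covariate or precision units
    K = _expected_information(beta, phi, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        score_scaled = float(np.max(np.abs(score) / np.sqrt(np.diag(K))))
    converged = score_max < tol or score_scaled < 1e-8
    if not converged and score_scaled > 1e-3:
        raise BetaConvergenceError(
            f"beta ML did not converge (max |score| = {score_max:.3g}, "
            f"scaled {score_scaled:.3g})",
            trajectory,
        )

    cov = np.linalg.inv(_expected_information(beta, phi, X))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore"):
        z = beta / se[:-1]
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    mu = expit(X @ beta)
    names = ["const"] + dataset.column_names
    return BetaFit(
        params=pd.Series(beta, index=names),
        phi=phi,
        bse=pd.Series(se[:-1], index=names),
        bse_phi=float(se[-1]),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        llf=_loglik(beta, phi, X, y, logy, log1y),
        mu=mu,
        eta=X @ beta,
        weights=working_weights(mu, phi),
        y=y,
        X=X,
        n=dataset.n,
        k_params=dataset.p + 2,
        converged=converged,
        score_max=score_max,
    )


def _expected_information(beta, phi, X):
    """Fisher information for (beta, phi) under the logit-link beta model."""
    mu = _mu(X, beta)
    a = mu * phi
    b = (1.0 - mu) * phi
    pa = polygamma(1, a)
    pb = polygamma(1, b)
    dmu = mu * (1.0 - mu)
    w = phi**2 * (pa + pb) * dmu**2
    c = phi * (pa * mu - pb * (1.0 - mu)) * dmu
    k_phi = float(np.sum(pa * mu**2 + pb * (1.0 - mu) ** 2
                         - polygamma(1, phi)))
    Kbb = X.T @ (w[:, None] * X)
    Kbp = X.T @ c
    m = X.shape[1]
    K = np.empty((m + 1, m + 1))
    K[:m, :m] = Kbb
    K[:m, m] = Kbp
    K[m, :m] = Kbp
    K[m, m] = k_phi
    return K


def working_weights(mu, phi) -> np.ndarray:
    """Fisher-information weights of the logit-link mean submodel.

    w_i = phi^2 [psi'(mu_i phi) + psi'((1-mu_i) phi)] (mu_i (1-mu_i))^2,
    so that X' diag(w) X is the expected information for beta at fixed phi.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    return phi**2 * (polygamma(1, a) + polygamma(1, b)) * (mu * (1.0 - mu)) ** 2


@dataclass
class BetaRidgeFit:
    """Ridge-shrunk beta regression coefficients."""

    k: float
    params: pd.Series
    ml_fit: BetaFit
    weights: np.ndarray
    theta_min: float
    theta_at_solution: float
    llf: float
    n: int
    k_params: int
    fittedvalues: np.ndarray
    label: str = "Beta Ridge"


def fit_beta_ridge(dataset: Dataset, k_policy=0.0, ml_fit: BetaFit | None = None) -> BetaRidgeFit:
    """Shrink the beta ML coefficients through the information geometry.

    ``k_policy`` is either a fixed non-negative constant or the string
    ``"hoerl_kennard_analogue"``, which sets k = (p+1) / (beta_ML' beta_ML)
    by direct analogy with the Hoerl-Kennard rule at unit link-scale
    dispersion.  The precision is held at its ML estimate; the reported
    log-likelihood is evaluated at (beta_BRR, phi_ML).
    """
    if ml_fit is None:
        ml_fit = fit_beta_ml(dataset)
    beta_ml = ml_fit.params.to_numpy()
    if isinstance(k_policy, str):
        if k_policy != "hoerl_kennard_analogue":
            raise ValueError(f"unknown k policy {k_policy!r}")
        k = (len(beta_ml)) / float(beta_ml @ beta_ml)
    else:
        k = float(k_policy)
        if k < 0:
            raise ValueError("shrinkage constant k must be >= 0")

    X = ml_fit.X
    w = ml_fit.weights
    A = X.T @ (w[:, None] * X)
    beta_brr = np.linalg.solve(A + k * np.eye(A.shape[0]), A @ beta_ml)

    # working-response decomposition: Theta(b) = Theta_min + (b - b_ML)' A (b - b_ML)
    mu = ml_fit.mu
    phi = ml_fit.phi
    ystar = np.log(ml_fit.y) - np.log1p(-ml_fit.y)
    mustar = digamma(mu * phi) - digamma((1.0 - mu) * phi)
    z_minus_eta = phi * (ystar - mustar) * mu * (1.0 - mu) / w
    theta_min = float(z_minus_eta @ (w * z_minus_eta))
    d = beta_brr - beta_ml
    theta_at = theta_min + float(d @ (A @ d))

    mu_brr = expit(X @ beta_brr)
    llf = float(np.sum(beta_logpdf(ml_fit.y, mu_brr, phi)))
    return BetaRidgeFit(
        k=k,
        params=pd.Series(beta_brr, index=ml_fit.params.index),
        ml_fit=ml_fit,
        weights=w,
        theta_min=theta_min,
        theta_at_solution=theta_at,
        llf=llf,
        n=ml_fit.n,
        k_params=ml_fit.k_params,
        fittedvalues=mu_brr,
    )


def saturated_mean(y, phi) -> np.ndarray:
    """Per-record likelihood-maximizing mean of the beta law.

    Unlike exponential-family deviances, the beta log-likelihood in mu is
    not maximized at mu = y; the optimum solves
    psi(mu phi) - psi((1-mu) phi) = logit(y).  Solved by Newton on the
    logit scale (the score is strictly decreasing in mu), starting at y.
    """
    y = np.asarray(y, dtype=float)
    ystar = logit(y)
    theta = logit(y).copy()  # logit of the running mean estimate
    for _ in range(100):
        mu = np.clip(expit(theta), 1e-12, 1.0 - 1e-12)
        a, b = mu * phi, (1.0 - mu) * phi
        g = ystar - (digamma(a) - digamma(b))
        dgdtheta = -phi * (polygamma(1, a) + polygamma(1, b)) * mu * (1.0 - mu)
        step = -g / dgdtheta
        theta = theta + np.clip(step, -4.0, 4.0)
        if np.max(np.abs(g)) < 1e-12:
            break
    return np.clip(expit(theta), 1e-12, 1.0 - 1e-12)


def beta_deviance_residuals(fit: BetaFit) -> np.ndarray:
    """Signed root of each record's deviance contribution.

    The saturated contribution evaluates the record's likelihood at its own
    maximizing mean, so every contribution is non-negative; tiny negative
    values from floating-point noise are clipped at zero.
    """
    ll_fit = beta_logpdf(fit.y, fit.mu, fit.phi)
    ll_sat = beta_logpdf(fit.y, saturated_mean(fit.y, fit.phi), fit.phi)
    gap = 2.0 * (ll_sat - ll_fit)
    if np.any(gap < -1e-10):
        raise FloatingPointError("negative deviance contribution beyond tolerance")
    gap = np.clip(gap, 0.0, np.inf)
    return np.sign(fit.y - fit.mu) * np.sqrt(gap)
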