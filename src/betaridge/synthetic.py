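"""Synthetic data generators.

Two emulators live here:

* Monte-Carlo datasets for the simulation study -- multivariate-normal
  predictors with exchangeable correlation and a beta-distributed response
  whose mean follows a logit-linear model.
* A download-free stand-in for the Breast Cancer Wisconsin Diagnostic table
  that reproduces its published per-feature moments and correlation
  structure, including the perimeter/area near-collinearity that motivates
  ridge-type estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data_io import Dataset

__all__ = [
    "SimulationConfig",
    "gen_correlation_matrix",
    "gen_mc_predictors",
    "gen_beta_response",
    "gen_wdbc_like",
]


@dataclass
class SimulationConfig:
    """Study conditions for one Monte-Carlo cell.

    Defaults are the simulation design of the study this package replicates:
    four standard-normal predictors with exchangeable correlation, a beta
    response with precision phi = 15 whose linear predictor has intercept 3
    and slopes 0.5, and 1000 replications.
    """

    n: int = 100
    p: int = 4
    rho: float = 0.7
    D: np.ndarray | None = None  # diagonal scaling; identity when None
    beta_true: np.ndarray = field(
        default_factory=lambda: np.array([3.0, 0.5, 0.5, 0.5, 0.5])
    )
    phi_true: float = 15.0
    reps: int = 1000
    ridge_k: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if len(self.beta_true) != self.p + 1:
            raise ValueError(
                f"beta_true must have length p + 1 = {self.p + 1} "
                "(intercept first)"
            )
        if self.phi_true <= 0:
            raise ValueError("phi_true must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.ridge_k < 0:
            raise ValueError("ridge_k must be >= 0")
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float).ravel()
            if len(self.D) != self.p or np.any(self.D <= 0):
                raise ValueError("D must be a positive vector of length p")

    @property
    def sigma(self) -> np.ndarray:
        """Predictor covariance Sigma = D^{1/2} R D^{1/2}."""
        R = gen_correlation_matrix(self.p, self.rho)
        if self.D is None:
            return R
        s = np.sqrt(self.D)
        return R * np.outer(s, s)


def gen_correlation_matrix(p: int, rho: float) -> np.ndarray:
    """Exchangeable correlation matrix: unit diagonal, off-diagonals rho.

    Eigenvalues are 1 + (p-1)rho (once) and 1 - rho (p-1 times), so the
    matrix is positive definite for any rho in [0, 1).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    R = np.full((p, p), rho, dtype=float)
    np.fill_diagonal(R, 1.0)
    return R


def gen_mc_predictors(config: SimulationConfig, rng=None) -> np.ndarray:
    """Draw the n x p predictor matrix from N(0, Sigma)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sigma = config.sigma
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("predictor covariance is not positive definite") from exc
    return rng.standard_normal((config.n, config.p)) @ L.T


def gen_beta_response(X, beta_true, phi_true: float, seed=None, rng=None) -> np.ndarray:
    """Draw y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi), logit-linear mean.

    ``beta_true`` carries the intercept first.  Output is strictly inside
    (0, 1); draws that underflow to the boundary are redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    if phi_true <= 0:
        raise ValueError("phi_true must be positive")
    eta = beta_true[0] + X @ beta_true[1:]
    mu = expit(eta)
    if np.any(mu <= 0) or np.any(mu >= 1):  # defensive: logit keeps mu interior
        raise ValueError("mean values must be strictly inside (0, 1)")
    y = rng.beta(mu * phi_true, (1.0 - mu) * phi_true)
    for _ in range(3):
        bad = (y <= 0.0) | (y >= 1.0)
        if not bad.any():
            break
        y[bad] = rng.beta(mu[bad] * phi_true, (1.0 - mu[bad]) * phi_true)
    # draws whose boundary distance underflows double precision (extreme
    # means with a tiny beta shape) are nudged to the nearest interior value
    return np.clip(y, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Diagnostic-table emulator
# ---------------------------------------------------------------------------

WDBC_COLUMNS = [
    "diagnosis",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave_points",
    "symmetry",
    "fractal_dimension",
]

# Published per-feature mean / standard deviation of the nine continuous
# cytology features (diagnosis is a 0/1 indicator with 37.3% malignant).
WDBC_MOMENTS = {
    "texture": (19.2896, 4.30104),
    "perimeter": (91.9690, 24.29898),
    "area": (654.8891, 351.91413),
    "smoothness": (0.0964, 0.01406),
    "compactness": (0.1043, 0.05281),
    "concavity": (0.0888, 0.07972),
    "concave_points": (0.0489, 0.03880),
    "symmetry": (0.1812, 0.02741),
    "fractal_dimension": (0.0628, 0.00706),
}

MALIGNANT_RATE = 0.373

# Published correlation matrix (diagnosis first, order as WDBC_COLUMNS).
_R = [
    [1.000, 0.415, 0.743, 0.709, 0.359, 0.597, 0.696, 0.777, 0.330, -0.013],
    [0.415, 1.000, 0.330, 0.321, -0.023, 0.237, 0.302, 0.293, 0.071, -0.076],
    [0.743, 0.330, 1.000, 0.987, 0.207, 0.557, 0.716, 0.851, 0.183, -0.261],
    [0.709, 0.321, 0.987, 1.000, 0.177, 0.499, 0.686, 0.823, 0.151, -0.283],
    [0.359, -0.023, 0.207, 0.177, 1.000, 0.659, 0.522, 0.554, 0.558, 0.585],
    [0.597, 0.237, 0.557, 0.499, 0.659, 1.000, 0.883, 0.831, 0.603, 0.565],
    [0.696, 0.302, 0.716, 0.686, 0.522, 0.883, 1.000, 0.921, 0.501, 0.337],
    [0.777, 0.293, 0.851, 0.823, 0.554, 0.831, 0.921, 1.000, 0.462, 0.167],
    [0.330, 0.071, 0.183, 0.151, 0.558, 0.603, 0.501, 0.462, 1.000, 0.480],
    [-0.013, -0.076, -0.261, -0.283, 0.585, 0.565, 0.337, 0.167, 0.480, 1.000],
]
WDBC_CORRELATION = np.array(_R)

#: gaussian noise added to perimeter/(2*pi) when building the radius response
RADIUS_NOISE_SD = 0.1


def nearest_correlation(R: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a rounded correlation matrix to positive definiteness.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized to
    one -- the standard nearest-PD practice for printed matrices.
    """
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    fixed = (V * np.maximum(w, eig_floor)) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.norm(fixed - R, ord="fro") > 0.05:
        raise ValueError("correlation matrix not repairable near the original")
    return fixed


def gen_wdbc_like(n: int, seed=None) -> Dataset:
    """Emulate the diagnostic table: published moments and correlations.

    A latent gaussian vector with the published 10 x 10 correlation matrix
    drives everything: the diagnosis indicator is a probit threshold on its
    first coordinate (so its correlation with perimeter tracks the published
    0.743), the nine continuous features are rescaled to the published
    means/SDs, and the radius response is perimeter / (2 pi) plus small
    gaussian noise, reproducing the near-collinearity of the real data.
    """
    if n < 20:
        raise ValueError("n must be at least 20")
    rng = np.random.default_rng(seed)
    R = nearest_correlation(WDBC_CORRELATION)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, 10)) @ L.T
    # redraw the (vanishingly rare) rows whose perimeter draw would be
    # non-positive, so the derived radius response stays positive
    m_per, s_per = WDBC_MOMENTS["perimeter"]
    for _ in range(100):
        bad = m_per + s_per * Z[:, 2] <= 1.0
        if not bad.any():
            break
        Z[bad] = rng.standard_normal((int(bad.sum()), 10)) @ L.T
    cols = {}
    cols["diagnosis"] = (Z[:, 0] > norm.ppf(1.0 - MALIGNANT_RATE)).astype(float)
    for j, name in enumerate(WDBC_COLUMNS[1:], start=1):
        m, s = WDBC_MOMENTS[name]
        cols[name] = m + s * Z[:, j]
    X = pd.DataFrame(cols, columns=WDBC_COLUMNS)
    radius = X["perimeter"].to_numpy() / (2.0 * np.pi) + RADIUS_NOISE_SD * (
        rng.standard_normal(n)
    )
    return Dataset(
        X,
        radius,
        family_hint="gaussian",
        response_name="radius",
        provenance=f"gen_wdbc_like(n={n}, seed={seed})",
    )
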