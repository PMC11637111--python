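"""Information criteria, multicollinearity diagnostics, model comparison.

AIC = -2 ln L + 2k and BIC = -2 ln L + k ln n, with k the number of
estimated parameters -- a real number for penalized smooths, where the
effective degrees of freedom take the place of a parameter count and the
log-likelihood is evaluated at the penalized estimate (the conditional AIC
convention for GAMs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Dataset

__all__ = [
    "aic",
    "bic",
    "gam_conditional_aic",
    "vif",
    "condition_number",
    "diagnose",
    "DiagnosticsReport",
    "SelectionReport",
    "compare_models",
]


def aic(loglik: float, k_params: float) -> float:
    """Akaike information criterion, -2 ln L + 2k."""
    if k_params <= 0:
        raise ValueError("k_params must be positive")
    return -2.0 * loglik + 2.0 * k_params


def bic(loglik: float, k_params: float, n: float) -> float:
    """Bayesian information criterion, -2 ln L + k ln n."""
    if k_params <= 0:
        raise ValueError("k_params must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    return -2.0 * loglik + k_params * np.log(n)


def gam_conditional_aic(fit) -> float:
    """Conditional AIC for a penalized fit.

    Uses the unpenalized log-likelihood at the penalized estimate and the
    effective degrees of freedom plus one scale/precision parameter.
    """
    return aic(fit.llf, fit.edf_total + 1.0)


def vif(X) -> pd.Series:
    """Variance inflation factors, 1 / (1 - R2_j) per predictor.

    Each column is regressed on all others plus an intercept.  Perfectly
    collinear columns report infinity rather than raising.
    """
    df = pd.DataFrame(X)
    vals = df.to_numpy(dtype=float)
    n, p = vals.shape
    out = np.empty(p)
    for j in range(p):
        xj = vals[:, j]
        others = np.column_stack([np.ones(n), np.delete(vals, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        tss = float(np.sum((xj - xj.mean()) ** 2))
        rss = float(resid @ resid)
        if tss == 0.0 or rss <= tss * 1e-14:
            out[j] = np.inf
        else:
            out[j] = tss / rss  # 1 / (1 - R2)
    return pd.Series(out, index=df.columns)


def condition_number(X, method: str = "design") -> float:
    """Condition number CN = sqrt(lambda_max / lambda_min).

    ``method="design"`` (default) scales the intercept-augmented design
    matrix to unit column length and takes the singular-value ratio -- the
    Belsley convention, under which the published diagnostic-table value is
    reproduced.  ``method="correlation"`` uses the eigenvalues of the
    predictor correlation matrix instead.
    """
    vals = pd.DataFrame(X).to_numpy(dtype=float)
    n, p = vals.shape
    if p < 2:
        raise ValueError("need at least two predictors")
    if np.any(vals.std(axis=0) == 0):
        raise ValueError("constant column in predictor matrix")
    if method == "design":
        A = np.column_stack([np.ones(n), vals])
        A = A / np.sqrt((A**2).sum(axis=0))
        sv = np.linalg.svd(A, compute_uv=False)
        if sv[-1] <= sv[0] * 1e-15:
            return np.inf
        return float(sv[0] / sv[-1])
    if method == "correlation":
        R = np.corrcoef(vals.T)
        ev = np.linalg.eigvalsh(R)
        if ev[-1] <= 0 or ev[0] <= ev[-1] * 1e-15:
            return np.inf
        return float(np.sqrt(ev[-1] / ev[0]))
    raise ValueError(f"unknown condition-number method {method!r}")


@dataclass
class DiagnosticsReport:
    correlation: pd.DataFrame
    vif: pd.Series
    condition_number: float
    eigenvalues: np.ndarray
    high_correlation_pairs: list = field(default_factory=list)
    high_vif: list = field(default_factory=list)

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues.max())

    @property
    def lambda_min(self) -> float:
        return float(self.eigenvalues.min())


def diagnose(
    dataset: Dataset,
    corr_threshold: float = 0.8,
    vif_threshold: float = 5.0,
    cn_method: str = "design",
) -> DiagnosticsReport:
    """Multicollinearity screen: correlations, VIF, condition number."""
    X = dataset.X
    R = X.corr()
    v = vif(X)
    vals = X.to_numpy(dtype=float)
    ev = np.linalg.eigvalsh(np.corrcoef(vals.T))
    pairs = [
        (R.index[i], R.columns[j], float(R.iloc[i, j]))
        for i in range(len(R))
        for j in range(i + 1, len(R))
        if abs(R.iloc[i, j]) > corr_threshold
    ]
    return DiagnosticsReport(
        correlation=R,
        vif=v,
        condition_number=condition_number(X, method=cn_method),
        eigenvalues=ev,
        high_correlation_pairs=pairs,
        high_vif=[name for name, val in v.items() if val > vif_threshold],
    )


@dataclass
class SelectionReport:
    table: pd.DataFrame
    aic_winner: str
    bic_winner: str


def compare_models(fits, n: int | None = None) -> SelectionReport:
    """AIC/BIC table across fitted models with the winner per criterion.

    ``fits`` maps labels to fit objects exposing ``llf`` and ``k_params``
    (a list of fits uses each fit's ``label``).  Ties break toward fewer
    parameters, then label order.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.label, f) for f in fits]
    if not items:
        raise ValueError("no models to compare")
    rows = []
    for label, f in items:
        nn = n if n is not None else f.n
        rows.append(
            {
                "model": label,
                "loglik": float(f.llf),
                "k_params": float(f.k_params),
                "AIC": aic(f.llf, f.k_params),
                "BIC": bic(f.llf, f.k_params, nn),
            }
        )
    table = pd.DataFrame(rows)

    def winner(col):
        order = table.sort_values(
            [col, "k_params", "model"], kind="stable"
        )
        return str(order.iloc[0]["model"])

    return SelectionReport(
        table=table, aic_winner=winner("AIC"), bic_winner=winner("BIC")
    )
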