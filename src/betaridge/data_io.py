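"""Reading and preparing diagnostic-table data.

The analyses in this package revolve around a tabular layout borrowed from
cytopathology: one row per patient, a categorical diagnosis (benign ``B`` /
malignant ``M``) and a set of continuous cell-morphology features.  The
response may be modelled on its raw scale (gaussian family) or rescaled into
the open unit interval for beta-family models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_table",
    "load_reference_table",
    "encode_diagnosis",
    "prepare_beta_response",
    "standardize_predictors",
]


@dataclass
class Dataset:
    """Analysis-ready predictor matrix plus response vector.

    Parameters
    ----------
    X : pandas.DataFrame
        Numeric predictor matrix with named columns and no missing entries.
    y : numpy.ndarray
        Response vector, same length as ``X``.
    family_hint : {"gaussian", "unit_interval"}
        Intended response family.  ``unit_interval`` requires every response
        value strictly inside (0, 1).
    response_name : str
        Name of the response column (used when writing back to disk).
    provenance : str
        Free-text source tag (file path, generator description, ...).
    """

    X: pd.DataFrame
    y: np.ndarray
    family_hint: str = "gaussian"
    response_name: str = "y"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = pd.DataFrame(self.X).copy()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.family_hint not in ("gaussian", "unit_interval"):
            raise ValueError(f"unknown family_hint {self.family_hint!r}")
        if len(self.X) != len(self.y):
            raise ValueError(
                f"X has {len(self.X)} rows but y has {len(self.y)} entries"
            )
        if self.X.columns.duplicated().any():
            dups = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate predictor names: {dups}")
        if self.X.isna().to_numpy().any() or np.isnan(self.y).any():
            raise ValueError("missing values are not allowed in a Dataset")
        if self.family_hint == "unit_interval":
            if self.y.size and (self.y.min() <= 0.0 or self.y.max() >= 1.0):
                raise ValueError(
                    "unit_interval response must lie strictly inside (0, 1); "
                    f"observed range [{self.y.min()}, {self.y.max()}]"
                )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, self.response_name, self.y)
        return out

    def to_csv(self, path) -> None:
        """Write response + predictors; floats round-trip bit-identically."""
        self.to_frame().to_csv(path, index=False)


def load_table(path, response_column: str, predictor_columns) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`.

    Rows with a missing value in any requested column abort the load (no
    silent dropping, no imputation).  Non-numeric cells are reported with
    their row number and column name.
    """
    predictor_columns = list(predictor_columns)
    try:
        # round_trip parsing keeps written floats bit-identical on re-load
        raw = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    wanted = [response_column] + predictor_columns
    missing = [c for c in wanted if c not in raw.columns]
    if missing:
        raise KeyError(f"columns missing from {path}: {missing}")
    sub = raw[wanted]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sub.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {sub.iat[r, c]!r} in column "
            f"{sub.columns[c]!r}, data row {r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in column {numeric.columns[c]!r}, data row {r}"
        )
    p = len(predictor_columns)
    if len(numeric) < p + 2:
        raise ValueError(
            f"need at least p + 2 = {p + 2} complete rows, got {len(numeric)}"
        )
    return Dataset(
        X=numeric[predictor_columns],
        y=numeric[response_column].to_numpy(),
        family_hint="gaussian",
        response_name=response_column,
        provenance=str(path),
    )


#: Kaggle/UCI-style column names for the ten mean-value cytology features.
REFERENCE_PREDICTORS = [
    "diagnosis",
    "texture_mean",
    "perimeter_mean",
    "area_mean",
    "smoothness_mean",
    "compactness_mean",
    "concavity_mean",
    "concave points_mean",
    "symmetry_mean",
    "fractal_dimension_mean",
]


def load_reference_frame() -> pd.DataFrame:
    """The Breast Cancer Wisconsin Diagnostic table (569 records).

    Returns the bundled copy distributed with scikit-learn, restricted to the
    diagnosis label and the ten mean-value features, with Kaggle/UCI-style
    column names.  ``diagnosis`` is returned as the raw ``B``/``M`` label.
    """
    from sklearn.datasets import load_breast_cancer

    d = load_breast_cancer(as_frame=True)
    df = d.frame
    out = pd.DataFrame(
        {
            # sklearn codes target 0 = malignant, 1 = benign
            "diagnosis": np.where(df["target"] == 0, "M", "B"),
            "radius_mean": df["mean radius"],
            "texture_mean": df["mean texture"],
            "perimeter_mean": df["mean perimeter"],
            "area_mean": df["mean area"],
            "smoothness_mean": df["mean smoothness"],
            "compactness_mean": df["mean compactness"],
            "concavity_mean": df["mean concavity"],
            "concave points_mean": df["mean concave points"],
            "symmetry_mean": df["mean symmetry"],
            "fractal_dimension_mean": df["mean fractal dimension"],
        }
    )
    return out


def load_reference_table(
    beta_scale: float | None = None, benign: float = 0.0, malignant: float = 1.0
) -> Dataset:
    """Analysis-ready reference dataset with ``radius_mean`` as response.

    Parameters
    ----------
    beta_scale : float, optional
        If given, the response is divided by this scale and the dataset is
        tagged ``unit_interval`` (for beta-family models).
    benign, malignant : float
        Numeric codes for the diagnosis label (default B=0, M=1).
    """
    df = load_reference_frame()
    X = df[REFERENCE_PREDICTORS].copy()
    X["diagnosis"] = encode_diagnosis(
        df["diagnosis"], benign=benign, malignant=malignant
    )
    y = df["radius_mean"].to_numpy()
    if beta_scale is None:
        return Dataset(X, y, "gaussian", "radius_mean", "sklearn:breast_cancer")
    return Dataset(
        X,
        prepare_beta_response(y, beta_scale),
        "unit_interval",
        "radius_mean",
        "sklearn:breast_cancer",
    )


def encode_diagnosis(labels, benign: float = 0.0, malignant: float = 1.0) -> np.ndarray:
    """Encode a B/M diagnosis label numerically (default B=0, M=1)."""
    arr = np.asarray(labels, dtype=object).ravel()
    out = np.empty(arr.shape, dtype=float)
    for i, v in enumerate(arr):
        if v == "B":
            out[i] = benign
        elif v == "M":
            out[i] = malignant
        else:
            raise ValueError(f"unknown diagnosis level {v!r}; expected 'B' or 'M'")
    return out


def prepare_beta_response(raw, scale: float) -> np.ndarray:
    """Map a positive response into (0, 1) by dividing by ``scale``."""
    raw = np.asarray(raw, dtype=float).ravel()
    if np.any(raw <= 0):
        raise ValueError("raw response values must all be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = raw / scale
    if out.max() >= 1.0 or out.min() <= 0.0:
        raise ValueError(
            f"scaled response not strictly inside (0, 1) (max {out.max()}); "
            "choose a scale larger than max(raw)"
        )
    return out


def standardize_predictors(X, method: str = "unit_length"):
    """Center predictors and scale them to correlation form.

    With the default unit-length convention each centered column is divided
    by the square root of its sum of squares, so the cross-product ``Z'Z`` of
    the standardized matrix equals the correlation matrix of ``X`` -- the
    coordinate system in which ridge shrinkage theory is usually stated.
    ``method="zscore"`` divides by the sample standard deviation instead.

    Returns
    -------
    (Z, center, scale)
        ``Z`` standardized matrix (ndarray), ``center`` column means,
        ``scale`` per-column divisors, allowing exact back-transformation.
    """
    df = pd.DataFrame(X)
    vals = df.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    centered = vals - center
    if method == "unit_length":
        scale = np.sqrt((centered**2).sum(axis=0))
    elif method == "zscore":
        scale = centered.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    zero = np.isclose(scale, 0.0)
    if zero.any():
        name = df.columns[int(np.argmax(zero))]
        raise ValueError(f"constant column {name!r} cannot be standardized")
    return centered / scale, center, scale
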