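import numpy as np
import pandas as pd
import pytest

from betaridge.data_io import Dataset, load_reference_table
from betaridge.synthetic import gen_wdbc_like


@pytest.fixture(scope="session")
def wdbc_like():
    """Emulated diagnostic table, moderate size."""
    return gen_wdbc_like(600, seed=7)


@pytest.fixture(scope="session")
def reference_data():
    """The bundled 569-record diagnostic table (gaussian response)."""
    return load_reference_table()


@pytest.fixture(scope="session")
def reference_unit():
    """Bundled table with the response rescaled into (0, 1)."""
    return load_reference_table(beta_scale=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_beta_dataset(rng):
    """Small simulated beta-response dataset with mild collinearity."""
    n, p = 120, 3
    R = np.full((p, p), 0.5)
    np.fill_diagonal(R, 1.0)
    X = rng.standard_normal((n, p)) @ np.linalg.cholesky(R).T
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.2])
    mu = 1.0 / (1.0 + np.exp(-eta))
    y = rng.beta(mu * 10.0, (1.0 - mu) * 10.0)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)
    return Dataset(
        pd.DataFrame(X, columns=["x1", "x2", "x3"]),
        y,
        family_hint="unit_interval",
    )
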