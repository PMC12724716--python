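import numpy as np
import pandas as pd
import pytest

from mitocross.genotypes import impute_genotypes
from mitocross.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_small_config():
    """Default cohort structure with a small gene panel for speed."""
    return SimConfig(n_genes=80, seed=11)


@pytest.fixture(scope="session")
def small_dataset(default_small_config):
    return generate_dataset(default_small_config)


@pytest.fixture(scope="session")
def genotypes63(small_dataset):
    return impute_genotypes(small_dataset.strain_table, small_dataset.marker_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def ols_normal_equations(y, X):
    """Independent OLS oracle: solve X'X b = X'y directly and form the
    classical t statistics.  Used to cross-check the scan engine."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    s2 = float(resid @ resid) / (n - p)
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, resid
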