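import numpy as np
import pandas as pd
import pytest

import smallgee as sg
from smallgee.data_model import ClusterBlock
from smallgee.working_correlation import CorrelationModel

WHEEZE_FORMULA = "Wheeze ~ City + C(Age)"


@pytest.fixture(scope="session")
def wheeze_df() -> pd.DataFrame:
    """Synthetic 16-child x 4-visit dataset with the wheeze-study schema."""
    return sg.wheeze_like_fixture(seed=0)


@pytest.fixture(scope="session")
def wheeze_design(wheeze_df):
    return sg.prepare(wheeze_df, WHEEZE_FORMULA, id="ID", repeated="Age")


@pytest.fixture(scope="session")
def wheeze_gee_fit(wheeze_design):
    return sg.fit_gee(wheeze_design, corstr="ar1")


def make_blocks(K=5, n=2, p=2, seed=1, beta=None):
    """Random small clustered problem as raw blocks (intercept + normals)."""
    r = np.random.default_rng(seed)
    if beta is None:
        beta = np.zeros(p)
    blocks = []
    for i in range(K):
        X = np.column_stack([np.ones(n)] + [r.normal(size=n) for _ in range(p - 1)])
        mu = 1.0 / (1.0 + np.exp(-X @ beta))
        y = (r.random(n) < mu).astype(float)
        blocks.append(ClusterBlock(i, y, X, np.arange(n), np.arange(n)))
    return blocks


@pytest.fixture
def toy_blocks():
    return make_blocks(K=5, n=2, p=2, seed=1)


@pytest.fixture
def toy_corr():
    return CorrelationModel(kind="exchangeable", alpha=0.3, phi=1.3, n_occasions=2)


def size1_design(n=40, seed=11, p=3):
    """Independent observations as size-1 clusters (logistic-regression shape)."""
    r = np.random.default_rng(seed)
    cols = {"id": np.arange(n)}
    X = [np.ones(n)]
    terms = []
    for j in range(1, p):
        x = r.normal(size=n) if j % 2 else (r.random(n) < 0.5).astype(float)
        cols[f"x{j}"] = x
        X.append(x)
        terms.append(f"x{j}")
    X = np.column_stack(X)
    beta = np.linspace(-0.4, 0.6, p)
    mu = 1.0 / (1.0 + np.exp(-X @ beta))
    cols["y"] = (r.random(n) < mu).astype(float)
    df = pd.DataFrame(cols)
    return sg.prepare(df, "y ~ " + " + ".join(terms), id="id")


@pytest.fixture
def independent_design():
    return size1_design()


@pytest.fixture
def separated_design():
    """Complete separation: the covariate predicts the outcome exactly."""
    n = 20
    x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    df = pd.DataFrame({"id": np.arange(n), "y": x.copy(), "x": x})
    return sg.prepare(df, "y ~ x", id="id")
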