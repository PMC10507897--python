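import numpy as np
import pandas as pd
import pytest

from rvimp import CLASSIFICATION, REGRESSION, TabularDataset


def make_regression(n=120, p=4, seed=0, beta=None, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(2, p)] = [2.0, -1.0][: min(2, p)]
    y = X @ beta + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(p)])
    return TabularDataset(df, y, REGRESSION)


def make_classification(n=120, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    lin = X[:, 0] * 1.5 - X[:, 1]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(float)
    df = pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(p)])
    return TabularDataset(df, y, CLASSIFICATION)


@pytest.fixture
def small_regression():
    return make_regression(n=80, p=3, seed=11)


@pytest.fixture
def small_classification():
    return make_classification(n=80, p=3, seed=12)
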