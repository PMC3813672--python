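import numpy as np
import pandas as pd
import pytest

import kpath


@pytest.fixture(scope="session")
def frame():
    """Canonical analysis matrix built from the packaged study tables."""
    return kpath.analysis_frame()


@pytest.fixture(scope="session")
def zmat(frame):
    return kpath.zscore(frame, frame.columns.tolist())


@pytest.fixture(scope="session")
def corr(zmat):
    return kpath.pearson_matrix(zmat)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_regression_frame(rng, n=40, p=4):
    """Random predictors with moderate correlation and a linear response."""
    A = rng.standard_normal((p, p))
    cov = A @ A.T + p * np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    beta = rng.uniform(-1.0, 1.0, size=p)
    y = X @ beta + rng.standard_normal(n)
    cols = [f"x{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df["y"] = y
    return df, cols
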