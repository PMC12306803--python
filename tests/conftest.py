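import numpy as np
import pytest

from fgee.data import FunctionalDataset


def make_dataset(N=4, n_i=3, L=6, q=1, seed=0, family="gaussian",
                 theta_scale=0.5):
    """Small random dataset with smooth-ish signal, for unit tests."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, L)
    n = np.full(N, n_i)
    M = N * n_i
    X = rng.standard_normal((M, q)) if q else np.empty((M, 0))
    eta = (np.sin(2 * np.pi * grid)[None, :] * theta_scale
           + (X.sum(axis=1)[:, None] if q else 0.0) * np.cos(np.pi * grid))
    if family == "gaussian":
        Y = eta + rng.standard_normal((M, L))
    elif family == "binomial":
        Y = (rng.random((M, L)) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        Y = rng.poisson(np.exp(eta)).astype(float)
    return FunctionalDataset(grid=grid, cluster_ids=np.arange(N), n=n,
                             Y=Y, X=X, family=family)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_gaussian():
    return make_dataset(N=5, n_i=4, L=8, q=1, seed=3)
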