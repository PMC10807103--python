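import numpy as np
import pytest

import pchclust as pc
from pchclust.prior import build_pair_index, to_partition


@pytest.fixture(scope="session")
def worked_prior():
    """The eight-sample must-link example: pairs {(1,2),(1,4),(2,4),(5,6)}
    in 1-based notation, blocks {1,2,4},{3},{5,6},{7},{8}."""
    return pc.validate_and_close([(0, 1), (0, 3), (1, 3), (4, 5)], 8)


@pytest.fixture(scope="session")
def small_data():
    """n=8 random dataset for exact-oracle comparisons."""
    rng = np.random.default_rng(42)
    return pc.HierarchicalDataset(X=rng.normal(size=(3, 8)), Z=rng.normal(size=(4, 8)))


@pytest.fixture(scope="session")
def separated_data():
    """Two well-separated rough masses, each with two refined sub-masses."""
    rng = np.random.default_rng(0)
    n_per = 10
    X_cols, Z_cols, rough, refined = [], [], [], []
    for r, xc in enumerate([-4.0, 4.0]):
        for t, zc in enumerate([-4.0, 4.0]):
            X_cols.append(xc + 0.01 * rng.standard_normal((2, n_per)))
            Z_cols.append(zc * (1 if r == 0 else -1)
                          + 0.01 * rng.standard_normal((3, n_per)))
            rough += [r] * n_per
            refined += [2 * r + t] * n_per
    data = pc.HierarchicalDataset(X=np.hstack(X_cols), Z=np.hstack(Z_cols))
    return data, np.array(rough), np.array(refined)


def fit_and_extract(data, prior, lam1, lam2, **cfg_kw):
    config = pc.SolverConfig(**cfg_kw)
    state = pc.fit(data, prior, lam1, lam2, config)
    pairs = build_pair_index(data.n, prior)
    return state, pc.extract(state, pairs)
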