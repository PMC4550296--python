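import numpy as np
import pytest

from stickdpm import Dataset, PriorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_data():
    """n=6 covariate-only binary fixture with a planted 2-block split."""
    from stickdpm.synthetic_data import gen_tiny_fixture

    return gen_tiny_fixture(6, 2, np.random.default_rng(0))


@pytest.fixture
def response_data(rng):
    """Small profile-regression dataset with response and one fixed effect."""
    n = 60
    z = np.repeat([0, 1], n // 2)
    X = np.where(rng.uniform(size=(n, 3)) < np.where(z == 0, 0.85, 0.15)[:, None],
                 0, 1)
    W = rng.standard_normal((n, 1))
    eta = np.where(z == 0, -1.0, 1.0) + 0.8 * W[:, 0]
    Y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
    return Dataset(X=X, Y=Y, W=W, K=np.full(3, 2, dtype=np.int64))


@pytest.fixture
def flat_priors():
    return PriorSpec(alpha_fixed=1.0)
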