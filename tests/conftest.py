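import numpy as np
import pytest

from zinbmm.core_model import BatchDesign, CountMatrix, ZinbmmParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)


@pytest.fixture
def toy_counts():
    """5 cells x 3 genes with a mix of zeros and positive counts."""
    values = np.array([
        [0, 3, 7],
        [2, 0, 1],
        [0, 0, 4],
        [5, 1, 0],
        [1, 2, 9],
    ])
    return CountMatrix(values)


@pytest.fixture
def toy_batches():
    return BatchDesign.from_labels(["a", "a", "b", "b", "b"])


@pytest.fixture
def toy_params(rng):
    """Valid 2-cluster parameters for the 3-gene toy data."""
    J, K, S = 3, 2, 2
    return ZinbmmParams(
        p=np.array([0.6, 0.4]),
        pi=rng.uniform(0.05, 0.5, size=(J, K)),
        beta=rng.normal(1.0, 0.5, size=(J, K)),
        phi=rng.uniform(0.5, 5.0, size=J),
        gamma=np.array([0.0, 0.3]),
        beta_star=rng.normal(1.0, 0.5, size=J),
    )


def two_cluster_counts(n=80, J=40, delta=1.5, seed=0, pi_drop=0.1):
    """Small two-cluster ZINB dataset with known labels (direct generation,
    independent of the simulate module)."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    mu_base = rng.uniform(2.0, 20.0, size=J)
    shift = np.where(rng.random(J) < 0.5, delta, -delta)
    mu = np.where(labels[:, None] == 0, mu_base[None, :],
                  mu_base[None, :] * np.exp(shift)[None, :])
    phi = rng.uniform(1.0, 5.0, size=J)
    lam = rng.gamma(shape=phi[None, :], scale=mu / phi[None, :])
    x = rng.poisson(lam)
    x[rng.random((n, J)) < pi_drop] = 0
    X = CountMatrix(x)
    B = BatchDesign(np.ones((n, 1)))
    return X, B, labels + 1
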