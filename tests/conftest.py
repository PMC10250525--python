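import numpy as np
import pytest

from ordgmm.design import (
    Condition,
    GaussianComponent,
    MixtureDesign,
    build_design,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k2p2_design(rng):
    """Well-separated two-component bivariate design."""
    return build_design(Condition(K=2, p=2, target_kl=5.0, N=1000), rng)


@pytest.fixture
def k3p4_design(rng):
    return build_design(Condition(K=3, p=4, target_kl=3.5, N=1000), rng)


def random_spd(rng, p, scale=1.0):
    a = rng.standard_normal((p, p))
    return scale * (a @ a.T + p * np.eye(p))


def make_design(means, cov, target_kl=1.0):
    """Shared-covariance design from explicit means (testing helper)."""
    means = np.asarray(means, dtype=float)
    K = means.shape[0]
    comps = tuple(
        GaussianComponent(means[k], cov, 1.0 / K) for k in range(K)
    )
    return MixtureDesign(K=K, p=means.shape[1], components=comps,
                        target_kl=target_kl, kl_tolerance=np.inf)
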