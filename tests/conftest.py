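import numpy as np
import pytest

from hfqnet.network import NetworkSpec


def make_random_spec(rng: np.random.Generator, n: int, m: int,
                     dissociation: bool = True,
                     beta_overrides: dict | None = None) -> NetworkSpec:
    """A well-conditioned random network: O(1) productions, moderate rates."""
    kneg = (lambda *shape: rng.uniform(0.1, 5.0, shape)) if dissociation \
        else (lambda *shape: np.zeros(shape))
    return NetworkSpec(
        n_srna=n, m_mrna=m,
        alpha_H=rng.uniform(0.1, 5.0),
        alpha_S=rng.uniform(0.1, 2.0, n),
        alpha_T=rng.uniform(0.1, 2.0, m),
        beta=1.0,
        k1=rng.uniform(0.1, 20.0, n), kneg1=kneg(n),
        k2=rng.uniform(0.1, 20.0, m), kneg2=kneg(m),
        k3=rng.uniform(0.1, 20.0, (n, m)), kneg3=kneg(n, m),
        k4=rng.uniform(0.1, 20.0, (n, m)), kneg4=kneg(n, m),
        k5=rng.uniform(0.0, 10.0, (n, m)),
        beta_overrides=beta_overrides or {},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20110818)


@pytest.fixture
def single_pair_spec() -> NetworkSpec:
    """A simple cognate pair with balanced kinetics and some dissociation."""
    return NetworkSpec(
        n_srna=1, m_mrna=1, alpha_H=1.0, alpha_S=1.0, alpha_T=1.0, beta=1.0,
        k1=10.0, kneg1=1.0, k2=10.0, kneg2=1.0,
        k3=10.0, kneg3=1.0, k4=10.0, kneg4=1.0, k5=100.0,
    )
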