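import numpy as np
import pytest

from pauseflux import RateParams


@pytest.fixture
def example_params() -> RateParams:
    """The worked-example parameter set: p_ss=1, b_ss=0.005, P_i=200."""
    return RateParams(k_init=1.0, k_pre=0.5, k_rel=0.5, k_term=1.0, l_p=100, l_b=10_000)


def random_params(rng: np.random.Generator, allow_zero_kpre: bool = False) -> RateParams:
    """A random positive parameter set spanning two orders of magnitude."""
    k = 10.0 ** rng.uniform(-1, 1, size=4)
    if allow_zero_kpre and rng.random() < 0.2:
        k[1] = 0.0
    l_p = rng.uniform(20, 99)
    return RateParams(
        k_init=k[0], k_pre=k[1], k_rel=k[2], k_term=k[3], l_p=l_p, l_b=l_p * rng.uniform(20, 200)
    )
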