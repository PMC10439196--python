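import numpy as np
import pytest

from stochprey import Discretization, ModelParameters


@pytest.fixture
def base_params() -> ModelParameters:
    """Stable-coexistence parameter set (f=0.79)."""
    return ModelParameters(
        a=1.1, b=0.7, c=2.1, m=1.0, f=0.79, d=0.5,
        sigma1=0.1, sigma2=0.1, eta1=0.01, eta2=0.01,
    )


@pytest.fixture
def base_disc() -> Discretization:
    """Grid used with the stable-coexistence set: L=30, 100 intervals, dt=0.1."""
    return Discretization(30.0, 100, 0.1, 5000)


@pytest.fixture
def small_disc() -> Discretization:
    """Short cheap grid for step-level tests."""
    return Discretization(30.0, 20, 0.1, 50)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
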