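import numpy as np
import pytest
from hypothesis import settings

from ivdt2.phantom import PhantomSpec, render_echo_stack

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(noise_model="none")


@pytest.fixture(scope="session")
def noiseless_session(noiseless_spec):
    """One rendered noiseless default phantom session (stack, truth)."""
    return render_echo_stack(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_session():
    """One rendered session at the default Rician noise level."""
    spec = PhantomSpec(noise_sigma=20.0, seed=7)
    return render_echo_stack(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
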