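import numpy as np
import pytest

from motifsync import CouplingParams, OscillatorParams


@pytest.fixture(scope="session")
def paper_params() -> OscillatorParams:
    """Standard supercritical parameter set in the excitable regime."""
    return OscillatorParams(lambda0=-0.5, alpha=-0.2, gamma=-0.2, omega0=2.0, omega1=0.0)


@pytest.fixture(scope="session")
def uneven_coupling() -> CouplingParams:
    """Strongly uneven coupling: oscillator 1 receives the strong input."""
    return CouplingParams(d1=0.3, d2=0.01)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240223)
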