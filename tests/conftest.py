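import numpy as np
import pytest

from drivefc import SynthConfig, default_montage, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_session():
    """One default-condition synthetic session shared across tests."""
    return generate_session(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def quiet_session():
    """High-effect, outlier-free session for recovery-style checks."""
    return generate_session(
        SynthConfig(seed=11, effect_size=0.9, outlier_rate=0.0)
    )
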