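import numpy as np
import pytest

from birhythm import (
    BirhythmicConfig,
    integrate,
    prepare_on_attractor,
    z_fixed_point,
)


@pytest.fixture(scope="session")
def config():
    """Default birhythmic configuration (gamma = 50)."""
    return BirhythmicConfig()


@pytest.fixture(scope="session")
def quick_config():
    """Same attractor structure with a faster z subsystem, for cheap tests."""
    return BirhythmicConfig(gamma=5.0)


@pytest.fixture(scope="session")
def zstar():
    return z_fixed_point(1.5)


@pytest.fixture(scope="session")
def slow_state(config):
    """A state prepared on the slow limit cycle."""
    return prepare_on_attractor(config, np.array([0.6, -0.3, 0.7]))


@pytest.fixture(scope="session")
def fast_state(config):
    """A state prepared on the fast limit cycle."""
    return prepare_on_attractor(config, np.array([0.6, -0.3, -0.7]))


@pytest.fixture(scope="session")
def slow_traj(config, slow_state):
    """Unstimulated recording of ~6 slow periods."""
    return integrate(config, slow_state, None, (0.0, 100.0), dt_out=0.01)


@pytest.fixture(scope="session")
def fast_traj(config, fast_state):
    """Unstimulated recording of ~6 fast periods."""
    return integrate(config, fast_state, None, (0.0, 30.0), dt_out=0.01)
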