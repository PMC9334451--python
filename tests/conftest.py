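import numpy as np
import pytest

from phosvpl import ScreenGeometry, generate_field
from phosvpl.design import build_schedule, default_schedule


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry(1600, 900, 40.0 / 1600.0)


@pytest.fixture(scope="session")
def small_screen():
    """A coarse screen for pixel-exhaustive renderer oracles."""
    return ScreenGeometry(64, 48, 0.25)


@pytest.fixture(scope="session")
def field_1000():
    return generate_field(1000, 80.0, seed=7)


@pytest.fixture(scope="session")
def field_10():
    """Tiny field for brute-force renderer comparisons."""
    return generate_field(10, 8.0, seed=3)


@pytest.fixture(scope="session")
def schedule8():
    return build_schedule(8, seed=11)


@pytest.fixture(scope="session")
def packaged_schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
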