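from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from scindel.simulate import default_read_structure, synthetic_panel


@pytest.fixture(scope="session")
def small_panel():
    """Three-target synthetic panel shared by fast unit tests."""
    return synthetic_panel(n_targets=3, seed=11)


@pytest.fixture(scope="session")
def structure():
    return default_read_structure()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
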