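import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import micromot as mm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def island():
    """50x50 um island at 0.2 um/pixel, 15 um margin (the default assay scale)."""
    return mm.default_island()


@pytest.fixture(scope="session")
def partition(island):
    return mm.build_partition(island)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
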