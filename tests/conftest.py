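import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hodomap.volumes import VolumeGrid

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid2mm() -> VolumeGrid:
    """Small 2 mm isotropic grid centred on the x = 0 midline."""
    return VolumeGrid(shape=(10, 10, 10), spacing_mm=(2.0, 2.0, 2.0), origin_mm=(-9.0, -9.0, -9.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
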