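import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stemflux import ChamberSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def chamber() -> ChamberSpec:
    """LiCOR-style closed system: 5 L, 88.25 cm^2 collar, 3-min closure
    with a 90-s dead band."""
    return ChamberSpec(system_volume_cm3=5000.0, collar_area_cm2=88.25,
                       dead_band_s=90.0, closure_duration_s=180.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230501)
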