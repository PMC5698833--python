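import math

import pytest
from hypothesis import HealthCheck, settings

from corneashell import CornealGeometry, RunConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def typical_geom() -> CornealGeometry:
    """Healthy-adult cohort geometry: R 7.17 mm, CCT 543.1 um, dimple
    half-angle pi/6, near-incompressible stroma."""
    return CornealGeometry.from_clinical(7.17, 543.1, math.pi / 6, 0.49)


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()
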