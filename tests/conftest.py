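import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sproutscreen.geometry import ChipGeometry
from sproutscreen.synth import NoiseParams, RenderParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> ChipGeometry:
    """Default full-size chip geometry."""
    return ChipGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> ChipGeometry:
    """Compact chip used where rendering speed matters more than realism."""
    return ChipGeometry(channel_width=150.0, phaseguide_width=50.0,
                        sprout_region_depth=300.0, image_width=250.0,
                        pixel_size=0.65)


@pytest.fixture(scope="session")
def noise_default() -> NoiseParams:
    return NoiseParams()


@pytest.fixture(scope="session")
def render_default() -> RenderParams:
    return RenderParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
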