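import numpy as np
import pytest

from snellvis import CurvedDishGeometry, MediaStack, ScreenSpec, get_preset


@pytest.fixture(scope="session")
def dunn_stack() -> MediaStack:
    return get_preset("dunn2016")


@pytest.fixture(scope="session")
def temizer_dish() -> CurvedDishGeometry:
    return get_preset("temizer2015")


@pytest.fixture(scope="session")
def air_water() -> MediaStack:
    """Plain air|water, total 1 cm, ratio d_a/d_w = 0.1."""
    return MediaStack.air_water(d_a=10.0 / 11.0, d_w=100.0 / 11.0)


@pytest.fixture(scope="session")
def identity_stack() -> MediaStack:
    return MediaStack.identity(total_mm=10.0)


@pytest.fixture
def small_screen() -> ScreenSpec:
    """Coarse 4x4 cm screen for fast image tests."""
    return ScreenSpec(width_cm=4.0, height_cm=4.0, resolution=50.0)
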