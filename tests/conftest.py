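import numpy as np
import pytest

from fidkit import DeviceGeometry, PhantomSpec

# Compact device + scene used by volume-based tests: same topology as the
# default device (4 wheels, 10 stops, 3 collinear column markers) but small
# enough that the rendered volume stays a few-million voxels.
SMALL_GEOMETRY = DeviceGeometry(
    arm_radii_mm=(20.0, 26.0, 32.0, 38.0),
    collector_offsets_mm=(0.0, 6.0, 12.0),
)


@pytest.fixture
def geometry() -> DeviceGeometry:
    return DeviceGeometry.default()


@pytest.fixture
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        geometry=SMALL_GEOMETRY,
        wheel_axial_offsets_mm=(-6.0, -12.0, -18.0, -24.0),
        targets_mm=np.array([[15.0, -10.0, -25.0], [-20.0, 12.0, -20.0]]),
        volume_size=(192, 192, 128),
        spacing_mm=(0.5, 0.5, 0.5),
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
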