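import dataclasses

import numpy as np
import pytest

from fetalt2star.io import BinaryMask, EchoTimes, ScalarMap, VoxelGeometry
from fetalt2star.synthetic import PhantomSpec, STUDY_ECHO_TIMES


@pytest.fixture
def echoes() -> EchoTimes:
    return STUDY_ECHO_TIMES


@pytest.fixture
def small_geometry() -> VoxelGeometry:
    return VoxelGeometry(dims=(12, 12, 12), spacing=(2.5, 2.5, 2.5))


@pytest.fixture
def small_phantom_spec() -> PhantomSpec:
    """A reduced grid keeping phantom-based tests fast."""
    return dataclasses.replace(
        PhantomSpec(),
        dims=(40, 40, 40),
        placenta_radius_mm=28.0,
        placenta_thickness_mm=18.0,
        perturb_amplitude_mm=3.0,
        perturb_wavelength_mm=30.0,
        brain_radii_mm=(18.0, 16.0, 15.0),
        seed=5,
    )


def random_mask(geometry: VoxelGeometry, rng: np.random.Generator, p: float = 0.4) -> BinaryMask:
    data = (rng.random(geometry.dims) < p).astype(np.uint8)
    data[0, 0, 0] = 1  # guarantee non-empty
    return BinaryMask(data=data, geometry=geometry)


def scalar_map_from(data: np.ndarray, geometry: VoxelGeometry, units: str = "msec") -> ScalarMap:
    return ScalarMap(data=np.asarray(data, dtype=float), geometry=geometry, units=units)
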