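import numpy as np
import pytest

from tamon import ChirpSpec, DetectorArray, ImageGrid


@pytest.fixture(scope="session")
def chirp_spec() -> ChirpSpec:
    return ChirpSpec()


@pytest.fixture(scope="session")
def small_grid() -> ImageGrid:
    return ImageGrid(n_pixels=32, pixel_size=1e-3)


@pytest.fixture(scope="session")
def small_array() -> DetectorArray:
    return DetectorArray(n_elements=16, ring_diameter=0.3, fs=5e6)


@pytest.fixture(scope="session")
def medium_grid() -> ImageGrid:
    return ImageGrid(n_pixels=64, pixel_size=0.25e-3)


@pytest.fixture(scope="session")
def medium_array() -> DetectorArray:
    return DetectorArray(n_elements=128, ring_diameter=0.6, fs=5e6)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
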