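import numpy as np
import pytest

from osteoatlas.geometry import AcquisitionGeometry
from osteoatlas.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_geom() -> AcquisitionGeometry:
    """4 mFOVs x 4 beams -> a 4x4 tile grid (1952 px square panorama)."""
    return AcquisitionGeometry(beams_per_mfov=4, n_mfov=4, tile_width_px=512, tile_height_px=512, overlap_px=32)


@pytest.fixture(scope="session")
def tiny_geom() -> AcquisitionGeometry:
    """1 beam x 4 mFOVs -> a 2x2 tile grid (992 px square panorama)."""
    return AcquisitionGeometry(beams_per_mfov=1, n_mfov=4, tile_width_px=512, tile_height_px=512, overlap_px=32)


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(n_cells=12, noise_sd=0.0, ghost_fraction=0.0, seed=5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
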