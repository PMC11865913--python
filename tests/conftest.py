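import numpy as np
import pytest

from aphidscape.raster import LandscapeRaster
from aphidscape.insects import SamplingSeries


@pytest.fixture
def worked_series() -> SamplingSeries:
    """The reference field-year: aphid wave followed by enemy waves."""
    return SamplingSeries(
        site_id="F1",
        year=2017,
        days=np.array([0, 7, 14, 21, 28]),
        leaves=np.full(5, 100),
        nSA=np.array([0.0, 2.0, 10.0, 50.0, 20.0]),
        nLB=np.array([0.0, 0.0, 1.0, 4.0, 6.0]),
        nMM=np.array([0.0, 0.0, 0.0, 2.0, 5.0]),
    )


def random_raster(rng: np.random.Generator, size: int, n_classes: int, resolution: float = 30.0) -> LandscapeRaster:
    """Random categorical raster with classes 1..n_classes (no background)."""
    codes = rng.integers(1, n_classes + 1, size=(size, size))
    return LandscapeRaster(codes=codes.astype(np.int64), resolution=resolution)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
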