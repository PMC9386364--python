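import numpy as np
import pytest

from wtvi.raster_io import BandMap, PlotROI, ReflectanceCube, default_bandmap


@pytest.fixture
def rng():
    return np.random.default_rng(20220804)


@pytest.fixture
def bandmap12():
    return default_bandmap()


@pytest.fixture
def bandmap4():
    """Minimal band map covering the four working wavelengths."""
    return BandMap(((550, 0, 10), (670, 1, 10), (720, 2, 10), (800, 3, 10)))


@pytest.fixture
def small_cube(rng, bandmap4):
    pixels = rng.uniform(0.01, 0.9, size=(8, 8, 4))
    return ReflectanceCube(pixels=pixels, bandmap=bandmap4)


@pytest.fixture
def full_roi():
    return PlotROI(plot_id="full", row_min=0, col_min=0, row_max=8, col_max=8)


def constant_cube(value, bandmap, h=8, w=8):
    b = bandmap.n_bands
    return ReflectanceCube(pixels=np.full((h, w, b), value), bandmap=bandmap)
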