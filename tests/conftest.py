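import numpy as np
import pytest

from rseli.raster import GridTransform, RasterGrid
from rseli.scene import AtmosphericParams, PlanckConstants, Scene


@pytest.fixture
def transform_1km() -> GridTransform:
    """1000 m pixels in a projected frame."""
    return GridTransform(500000.0, 4800000.0, 1000.0, -1000.0)


@pytest.fixture
def make_grid(transform_1km):
    """Factory: wrap an array (or fill a constant) as a 1 km RasterGrid."""

    def _make(values, mask=None, shape=(4, 4)):
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 0:
            arr = np.full(shape, float(values))
        return RasterGrid(arr, transform_1km, mask)

    return _make


@pytest.fixture
def make_scene(transform_1km):
    """Factory: build a Scene from per-band constant or array values."""

    def _make(shape=(4, 4), atmos=None, planck=None, **band_values):
        bands = {}
        for role, v in band_values.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim == 0:
                arr = np.full(shape, float(v))
            bands[role] = RasterGrid(arr, transform_1km)
        return Scene(
            year=2000,
            bands=bands,
            atmos=atmos or AtmosphericParams(l_up=0.0, l_down=0.0, t=1.0),
            planck=planck or PlanckConstants(k1=774.8853, k2=1321.0789),
        )

    return _make
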