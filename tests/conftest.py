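import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from corridorscape.raster import RasterGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


def make_grid(values, mask=None, cell_size=1.0, origin_lon=0.0, origin_lat=None, name=""):
    """Small helper: raster with its NW corner at (origin_lon, origin_lat)."""
    values = np.asarray(values, dtype=float)
    if origin_lat is None:
        origin_lat = values.shape[0] * cell_size
    return RasterGrid(
        values=values,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=cell_size,
        mask=mask,
        name=name,
    )


@pytest.fixture
def grid_3x3():
    return make_grid(np.arange(9, dtype=float).reshape(3, 3))
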