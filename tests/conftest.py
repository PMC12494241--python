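import numpy as np
import pytest
from shapely.geometry import box

from geogain import (
    RasterGrid,
    SampleSet,
    StudyArea,
    VariogramModel,
)


@pytest.fixture
def spherical_vm():
    return VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_=50.0)


@pytest.fixture
def three_point_config():
    """The minimal asymmetric kriging configuration used across tests."""
    coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    values = np.array([1.0, 2.0, 3.0])
    return coords, values


@pytest.fixture
def square_area():
    return StudyArea(box(0.0, 0.0, 100.0, 100.0), crs=32632)


@pytest.fixture
def small_sampleset():
    rng = np.random.default_rng(11)
    n = 40
    x = rng.uniform(0, 100, n)
    y = rng.uniform(0, 100, n)
    v = rng.normal(50, 5, n)
    t = np.array(["T1", "T2"] * (n // 2), dtype=object)
    return SampleSet(x, y, v, t, crs=32632, variable_name="yield")


@pytest.fixture
def constant_grid():
    vals = np.full((4, 4), 5.0)
    return RasterGrid(origin_x=0.0, origin_y=4.0, pixel=1.0, values=vals,
                      nodata_mask=np.zeros_like(vals, dtype=bool), crs=32632)
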