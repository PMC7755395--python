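import numpy as np
import pytest

from neuroscales.projection import ParcelMap
from neuroscales.synthetic import generate_sa_map, make_sphere_geometry


@pytest.fixture(scope="session")
def geometry():
    """Default 180-parcel spherical geometry."""
    return make_sphere_geometry(180, seed=0)


@pytest.fixture(scope="session")
def small_geometry():
    """Small geometry for fast unit tests."""
    return make_sphere_geometry(60, points_per_parcel=3, seed=1)


@pytest.fixture(scope="session")
def smooth_map(geometry):
    """Spatially autocorrelated map (length scale 20 mm) on the 180-parcel sphere."""
    return generate_sa_map(geometry, 20.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def full_confidence_map(values, parcel_ids=None):
    values = np.asarray(values, float)
    if parcel_ids is None:
        parcel_ids = np.arange(values.size)
    return ParcelMap(parcel_ids, values, np.ones(values.size))
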