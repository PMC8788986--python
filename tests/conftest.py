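import numpy as np
import pytest

from medalloc.data import HospitalRecord
from medalloc.routing import GeoLocation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hospitals():
    """Three hand-built facilities with distinct marginal readiness."""
    return [
        HospitalRecord(
            id="A", name="Alpha", latitude=38.0, longitude=-77.0,
            rating=4, beds=40.0, death_rate=10.0, cost=60.0, patients=100,
        ),
        HospitalRecord(
            id="B", name="Beta", latitude=37.5, longitude=-78.0,
            rating=3, beds=20.0, death_rate=25.0, cost=55.0, patients=250,
        ),
        HospitalRecord(
            id="C", name="Gamma", latitude=37.0, longitude=-76.5,
            rating=5, beds=60.0, death_rate=40.0, cost=70.0, patients=50,
        ),
    ]


def square_locations(side_km_deg=1.0):
    """Four locations on an axis-aligned square near the equator, where one
    degree is ~111.19 km; used for closed-form tour-length checks."""
    coords = [(0.0, 0.0), (0.0, side_km_deg), (side_km_deg, side_km_deg),
              (side_km_deg, 0.0)]
    return [
        GeoLocation(id=f"p{i}", latitude=lat, longitude=lon,
                    patients=10.0, recovery_cost=5.0, rating=2.0)
        for i, (lat, lon) in enumerate(coords)
    ]


@pytest.fixture
def unit_square_locs():
    return square_locations()
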