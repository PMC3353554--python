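import datetime as dt

import numpy as np
import pytest

from phenokrig import PhenoDataset, SamplingPoint, Zone
from phenokrig.reference import cordoba_network


@pytest.fixture(scope="session")
def network():
    """The study's ten monitoring sites."""
    return cordoba_network()


def make_points(coords, altitudes=None):
    """Sampling points from an (n, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if altitudes is None:
        altitudes = np.full(len(coords), 100.0)
    return [
        SamplingPoint(
            id=f"P{i}", x=float(x), y=float(y), altitude=float(a), zone=Zone.TERMO
        )
        for i, ((x, y), a) in enumerate(zip(coords, altitudes))
    ]


def make_dataset(coords, values, date=dt.date(2004, 4, 23), altitudes=None):
    return PhenoDataset(
        date=date, points=make_points(coords, altitudes), values=np.asarray(values, float)
    )


@pytest.fixture
def random_dataset():
    """Factory for random datasets: n points uniform on a 10 km square."""

    def _make(n, seed, lo=0.5, hi=3.5):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10_000, (n, 2))
        values = rng.uniform(lo, hi, n)
        return make_dataset(coords, values)

    return _make
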