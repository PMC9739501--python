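import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishspectra.core_data import CatchRecord, Season

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    species: str = "spA",
    weight: float = 10.0,
    length: float = 10.0,
    site: str = "S1",
    season: Season = Season.WET,
) -> CatchRecord:
    return CatchRecord(
        site_id=site,
        season=season,
        species=species,
        body_length=length,
        body_weight=weight,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def three_fish():
    """Two fish of species A (10 g, 20 g) and one of B (5 g)."""
    return [
        make_record("A", 10.0),
        make_record("A", 20.0),
        make_record("B", 5.0),
    ]
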