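import datetime as dt

import numpy as np
import pytest

import indoorvoc as iv


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-home synthetic cohort shared by read-only tests."""
    spec = iv.default_spec(n_homes=60, seed=7)
    return spec, iv.generate_cohort(spec)


@pytest.fixture()
def one_home():
    """A fully specified single home for worked-example tests."""
    return iv.HomeSample(
        home_id="H001",
        sample_date=dt.date(2023, 6, 15),
        season="summer",
        urban=True,
        volume_raw=50.0 / 0.93,  # 50 m3 after the 7% furnishing reduction
        n_adults=2,
        n_children=0,
        occupancy_fraction=1.0,
        co2_indoor=1000.0,
        indoor_conc={"benzene": 1.0, "toluene": 3.0},
        outdoor_conc={"benzene": 0.5, "toluene": 1.0},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
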