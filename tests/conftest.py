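import datetime

import pytest

from greenkeeper.core import NitrogenCycleParams, WeatherDay
from greenkeeper.synthetic_green import ClimateConfig, RootZoneProfile


@pytest.fixture
def ncp():
    return NitrogenCycleParams()


@pytest.fixture
def zone_a():
    return RootZoneProfile.from_som("A", som_level=0.7)


@pytest.fixture
def zone_b():
    return RootZoneProfile.from_som("B", som_level=1.2)


@pytest.fixture
def climate():
    """Default Wisconsin-like synthetic season."""
    return ClimateConfig(seed=0)


@pytest.fixture
def constant20_climate():
    """Degenerate climate: every day exactly at the growth optimum."""
    return ClimateConfig(mean_peak_temp=20.0, temp_amplitude=0.0, temp_noise_sd=0.0, seed=0)


def make_weather(tavgs, start=datetime.date(2020, 5, 1)):
    """Neutral WeatherDay sequence with the given daily mean temperatures."""
    return [
        WeatherDay(
            date=start + datetime.timedelta(days=i),
            tmax=t + 4.0,
            tmin=t - 4.0,
            tavg=t,
            precip=0.0,
            rhmax=80.0,
            rhmin=50.0,
            rhavg=65.0,
            wind_avg=8.0,
            et=3.0,
        )
        for i, t in enumerate(tavgs)
    ]
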