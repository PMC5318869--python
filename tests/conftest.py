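import datetime as dt

import pytest

from awpm.crop import MAIZE
from awpm.et import DEFAULT_ET
from awpm.soil import LOAM, SoilProfileState
from awpm.weather import HETAO, WeatherDay, generate_weather


@pytest.fixture(scope="session")
def loam():
    return LOAM


@pytest.fixture(scope="session")
def maize():
    return MAIZE


@pytest.fixture(scope="session")
def hetao():
    return HETAO


@pytest.fixture(scope="session")
def season_2007():
    return dt.date(2007, 4, 20), dt.date(2007, 9, 24)


@pytest.fixture(scope="session")
def synthetic_season(season_2007):
    start, end = season_2007
    return generate_weather(HETAO, start, end, seed=1)


@pytest.fixture
def midsummer_day():
    """A fixed mid-summer forcing day used by the ET0 oracle tests."""
    return WeatherDay(date=dt.date(2007, 7, 15), tmax=31.0, tmin=18.0,
                      sunshine=10.5, rh_mean=45.0, wind2m=2.5, rain=0.0)


@pytest.fixture
def profile_at_fc(loam):
    """Soil column at field capacity, table at 150 cm."""
    return SoilProfileState(rd=30.0, rd_mx=90.0, theta1=loam.mfc,
                            theta2=loam.mfc, apwl=0.0, gwd=150.0)
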