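import datetime as dt

import pytest

from teacrop.metforcing import DailyWeather, SiteInfo
from teacrop.soilwater import SoilProfile
from teacrop.teasim import TeaCropParams
from teacrop.mlbench import build_feature_table
from teacrop.synthetic_data import gen_plot_samples


@pytest.fixture(scope="session")
def site():
    return SiteInfo()


@pytest.fixture(scope="session")
def soil():
    return SoilProfile()


@pytest.fixture(scope="session")
def crop():
    return TeaCropParams()


def make_constant_weather(n_days: int, tmin=15.0, tmax=30.0, rh=60.0,
                          rain=0.0, wind=2.0, srad=18.0,
                          start=dt.date(2019, 5, 1)):
    return [DailyWeather(date=start + dt.timedelta(days=i), tmin=tmin,
                         tmax=tmax, rh_mean=rh, rain=rain, wind2m=wind,
                         solar_rad=srad)
            for i in range(n_days)]


@pytest.fixture(scope="session")
def constant_weather():
    return make_constant_weather(120)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default synthetic plucking dataset shared across benchmark tests."""
    samples, truth = gen_plot_samples(seed=1)
    return samples, truth


@pytest.fixture(scope="session")
def synthetic_table(synthetic_dataset):
    samples, _ = synthetic_dataset
    return build_feature_table(samples)
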