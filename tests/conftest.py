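"""Shared fixtures: small synthetic experiments and random driver traces."""

from __future__ import annotations

import numpy as np
import pytest

import phenoproc as pp


@pytest.fixture(scope="session")
def small_config():
    return pp.GeneratorConfig(n_years=2, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    series, metadata = pp.generate_drivers(small_config)
    return series, metadata


@pytest.fixture(scope="session")
def default_experiment():
    config = pp.GeneratorConfig(seed=11)
    series, metadata = pp.generate_drivers(config)
    return config, series, metadata


def random_trace(rng: np.random.Generator, elevated_co2: bool = False):
    """One random but physically plausible enclosure-year driver trace."""
    doy = np.arange(-121, 366)
    mat = rng.uniform(0.0, 8.0)
    amp = rng.uniform(10.0, 18.0)
    coldest = rng.uniform(0.0, 40.0)
    temp = mat - amp * np.cos(2 * np.pi * (doy - coldest) / 365.0)
    temp = temp + rng.normal(0.0, 2.0, doy.size)
    lat = rng.uniform(40.0, 60.0)
    daylength = pp.compute_daylength(lat, doy)
    rh = np.clip(rng.normal(75.0, 8.0, doy.size), 20.0, 100.0)
    vpd = pp.compute_vpd(temp, rh)
    water = -5.0 - 20.0 * np.exp(-0.5 * ((doy - 215) / 60.0) ** 2) + rng.normal(0, 2, doy.size)
    co2 = np.full(doy.size, 400.0)
    if elevated_co2:
        co2 = co2 + 500.0 * ((doy >= 120) & (doy <= 280))
    from phenoproc.datatypes import SOIL_DEPTHS_CM, DriverSeries

    return DriverSeries(
        enclosure_id="T01",
        focal_year=2020,
        doy=doy,
        t_air=temp,
        t_soil={d: temp * np.exp(-d / 50.0) + mat * (1 - np.exp(-d / 50.0))
                for d in SOIL_DEPTHS_CM},
        water_table=water,
        co2=co2,
        daylength=daylength,
        vpd=vpd,
    )


@pytest.fixture(scope="session")
def random_traces():
    rng = np.random.default_rng(123)
    return [random_trace(rng, elevated_co2=bool(i % 2)) for i in range(10)]
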