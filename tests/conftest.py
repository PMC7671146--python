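"""Shared fixtures: one default-calibrated synthetic year reused across
microclimate, metabolism, IBM and acceptance tests."""

import numpy as np
import pandas as pd
import pytest

from hotrocks import config as cfgmod
from hotrocks import ibm, microclimate as mc
from hotrocks.tides import TideModel

ROCK_SEED = 1
SERIES_SEED = 101


@pytest.fixture(scope="session")
def default_cfg():
    return cfgmod.load_config()


@pytest.fixture(scope="session")
def tide_model(default_cfg):
    return TideModel.from_config(default_cfg["tide"])


@pytest.fixture(scope="session")
def calibration(default_cfg):
    return mc.MicroclimateCalibration.from_config(default_cfg["microclimate"])


@pytest.fixture(scope="session")
def rock_field(default_cfg):
    return mc.generate_rock_field(12, 12, seed=ROCK_SEED, config=default_cfg)


@pytest.fixture(scope="session")
def year_records(rock_field, calibration, tide_model):
    """Default-calibrated synthetic year, 12 MIZ + 12 HIZ rocks, 30-min."""
    return mc.simulate_temperature_series(
        rock_field, "2016-01-01", "2017-01-01", calibration, tide_model,
        seed=SERIES_SEED,
    )


@pytest.fixture(scope="session")
def daily_summaries(year_records, rock_field):
    return mc.summarize_daily(year_records, rock_field)


@pytest.fixture(scope="session")
def zone_of(rock_field):
    return {r.rock_id: r.zone for r in rock_field}


@pytest.fixture(scope="session")
def temperature_pools(daily_summaries):
    return ibm.build_temperature_pools(daily_summaries)
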