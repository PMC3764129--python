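"""Shared fixtures: small synthetic forcing sets and cohort parameters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from turtlehab.habitat_model import HabitatParams, habitat_index
from turtlehab.io_formats import GridField
from turtlehab.movement_model import SimConfig
from turtlehab.synthetic_data import ForcingSpec, make_forcing

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_forcing():
    """Quarter-year forcing on a 41x41 half-degree grid (fixed seed)."""
    spec = ForcingSpec(
        lon_min=170.0,
        lon_max=190.0,
        lat_min=20.0,
        lat_max=40.0,
        grid_step=0.5,
        time_start="2005-01-01",
        time_end="2005-07-01",
        seed=1,
    )
    return make_forcing(spec)


@pytest.fixture(scope="session")
def cohort_params():
    """30 cm cohort: optimum 17 degC, tolerance 1.5, MSS 1.1 bl/s."""
    return HabitatParams(t_opt=17.0, t_sd=1.5, mss=1.1, scl=30.0)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_release=2000)


@pytest.fixture(scope="session")
def small_habitat(small_forcing, cohort_params):
    return habitat_index(small_forcing["temp30m"], small_forcing["prey"], cohort_params)


@pytest.fixture()
def flat_grid():
    """Uniform time-constant field helper on a tiny grid."""

    def _make(value=17.0, nx=11, ny=11, nt=3, name="temp30m", land=None):
        lon = 180.0 + 0.5 * np.arange(nx)
        lat = 25.0 + 0.5 * np.arange(ny)
        time = pd.date_range("2005-01-01", periods=nt, freq="6D")
        vals = np.full((nt, ny, nx), float(value))
        if land is not None:
            vals[:, land[0], land[1]] = np.nan
        return GridField(name=name, lon=lon, lat=lat, time=time, values=vals)

    return _make
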