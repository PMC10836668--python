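"""Shared fixtures: small handcrafted frames and a session-wide noiseless
synthetic dataset with known ground truth."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pollenseason import season_metrics as sm
from pollenseason import synthetic_data as sd
from pollenseason.core_data import WEATHER_VARS, Dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_weather(
    start: str, temps, fill: float | None = None, **columns
) -> pd.DataFrame:
    """Contiguous daily weather frame starting at *start* with the given
    temperatures; other variables default to benign constants."""
    temps = np.asarray(temps, dtype=float)
    n = len(temps)
    idx = pd.date_range(start, periods=n, freq="D")
    defaults = {
        "H": 50.0, "Rf": 0.0, "Cc": 30.0, "Sd": 6.0,
        "Ws": 5.0, "Wd": 180.0, "Wg": 8.0,
    }
    data = {"T": temps}
    for var in WEATHER_VARS:
        if var == "T":
            continue
        data[var] = np.full(n, columns.get(var, defaults[var]), dtype=float)
    frame = pd.DataFrame(data, index=idx)
    frame.index.name = "date"
    return frame


def make_year_pollen(year: int, day_values: dict[int, float]) -> pd.DataFrame:
    """Full-calendar-year pollen frame with the given day-of-year values
    and zeros elsewhere."""
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    conc = np.zeros(len(idx))
    for doy, value in day_values.items():
        conc[doy - 1] = value
    frame = pd.DataFrame({"concentration": conc}, index=idx)
    frame.index.name = "date"
    return frame


@pytest.fixture(scope="session")
def noiseless():
    """15-season noiseless synthetic dataset (seed 1): the bundle,
    the ground-truth season days, and the observed season table."""
    ds, truth_seasons = sd.make_dataset(sd.ClimateConfig(seed=1), noise_cv=0.0)
    table = sm.season_table(ds.pollen)
    return ds, truth_seasons, table


@pytest.fixture(scope="session")
def train_years():
    return list(range(2004, 2016))
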