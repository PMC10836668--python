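"""Synthetic multi-year weather and pollen series with known ground truth.

The generator emulates an Islamabad-like subtropical-highland climate
(annual mean temperature ≈ 20.3 °C, cool winters around 9–10 °C,
mid-summer around 31 °C) and drives pollen release with the same
thermal-forcing equations the calibration pipeline fits: the season
start is the day sigmoid forcing accumulated from the onset F1 reaches
``M_start``, and the peak is the day the post-start clamped degree-day
sum reaches ``M_peak``.  Calibration on the generated data is therefore
a parameter-recovery problem with a known answer.  The ground-truth
start*/peak* days are computed here with plain per-day loops, written
independently of the vectorised pipeline implementation, so agreement
between the two is a meaningful check rather than a tautology.

The weather series starts on 1 October of the year before the first
scored season: the earliest accumulation onset in the calibration grid
is 1 October, so the first training season needs the preceding autumn.

Daily temperature is a sinusoidal annual cycle plus AR(1) noise; the
other seven variables follow simple bounded stochastic models (seasonal
means with Gaussian noise, Bernoulli–exponential rainfall, gamma wind
speed, uniform wind direction).  Each season's concentrations follow a
skewed bell — a concave rise from start* to a maximum of
``peak_magnitude`` at peak*, then a slower exponential decay — times
multiplicative lognormal noise of a chosen coefficient of variation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    Dataset,
    MonthDay,
    day_of_year,
    monthday_to_date,
    parse_monthday,
)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth phenology used to drive pollen release.

    Defaults sit inside the calibration grids (onset 31 Jan, steepness
    −0.25, threshold 15 °C; trigger 16 °C, base 11 °C) with forcing
    requirements — 14.7 sigmoid units for the start, 34.0 °C·day for the
    peak — that place the mean season start near 8 March under the
    default climate.
    """

    F1: MonthDay = (1, 31)
    d: float = -0.25
    c: float = 15.0
    M_start: float = 14.7
    T_D: float = 16.0
    Th: float = 11.0
    M_peak: float = 34.0
    season_length: int = 45
    peak_magnitude: float = 40_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "F1", parse_monthday(self.F1))
        if not self.d < 0:
            raise ValueError(f"d must be negative, got {self.d}")
        if not self.M_start > 0 or not self.M_peak > 0:
            raise ValueError("forcing requirements must be positive")
        if not self.peak_magnitude > 0:
            raise ValueError("peak_magnitude must be positive")
        if self.season_length < 5:
            raise ValueError("season_length must be at least 5 days")


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the daily weather simulator (units as in the data
    contract: °C, %, mm, hours, km/h, degrees)."""

    n_years: int = 15
    start_year: int = 2004
    seed: int = 0
    # temperature: sinusoid + AR(1)
    annual_mean_T: float = 20.3
    annual_amplitude_T: float = 11.0
    ar1_rho: float = 0.7
    noise_sd_T: float = 1.5
    # humidity: winter-humid sinusoid
    mean_H: float = 55.0
    amplitude_H: float = 10.0
    noise_sd_H: float = 8.0
    # rainfall: Bernoulli wet days with exponential amounts
    p_wet: float = 0.15
    mean_rain: float = 6.0
    # cloud cover
    mean_Cc: float = 40.0
    amplitude_Cc: float = 15.0
    noise_sd_Cc: float = 15.0
    # sunshine duration
    mean_Sd: float = 7.0
    amplitude_Sd: float = 2.0
    noise_sd_Sd: float = 1.5
    # wind
    ws_shape: float = 2.0
    ws_scale: float = 4.0
    gust_factor: float = 1.6
    gust_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError(f"n_years must be >= 2, got {self.n_years}")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho}")
        for name in ("noise_sd_T", "noise_sd_H", "noise_sd_Cc", "noise_sd_Sd",
                     "gust_noise_sd", "mean_rain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_wet <= 1:
            raise ValueError(f"p_wet must lie in [0, 1], got {self.p_wet}")


def _annual_cycle(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    return mean - amplitude * np.cos(2 * np.pi * doy / 365.0)


def simulate_weather(config: ClimateConfig) -> Dataset:
    """Simulate daily weather from 1 Oct (start_year − 1) through 31 Dec
    of the last year.  Identical config (incl. seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    first = dt.date(config.start_year - 1, 10, 1)
    last = dt.date(config.start_year + config.n_years - 1, 12, 31)
    dates = pd.date_range(first, last, freq="D")
    doy = np.array([day_of_year(d) for d in dates], dtype=float)
    n = len(dates)

    # temperature: seasonal cycle + AR(1) noise
    innov = rng.normal(0.0, config.noise_sd_T, size=n)
    noise = np.empty(n)
    prev = 0.0
    for k in range(n):
        prev = config.ar1_rho * prev + innov[k]
        noise[k] = prev
    T = _annual_cycle(doy, config.annual_mean_T, config.annual_amplitude_T) + noise

    # winter-humid relative humidity (anti-phase with temperature)
    H = np.clip(
        _annual_cycle(doy, config.mean_H, -config.amplitude_H)
        + rng.normal(0.0, config.noise_sd_H, size=n),
        0.0, 100.0,
    )
    wet = rng.random(n) < config.p_wet
    Rf = np.where(wet, rng.exponential(config.mean_rain or 1e-12, size=n), 0.0)
    Cc = np.clip(
        _annual_cycle(doy, config.mean_Cc, -config.amplitude_Cc)
        + rng.normal(0.0, config.noise_sd_Cc, size=n),
        0.0, 100.0,
    )
    Sd = np.clip(
        _annual_cycle(doy, config.mean_Sd, config.amplitude_Sd)
        + rng.normal(0.0, config.noise_sd_Sd, size=n),
        0.0, 24.0,
    )
    Ws = rng.gamma(config.ws_shape, config.ws_scale, size=n)
    Wd = rng.uniform(0.0, 360.0, size=n) % 360.0
    Wg = Ws * config.gust_factor + np.abs(
        rng.normal(0.0, config.gust_noise_sd, size=n)
    )

    weather = pd.DataFrame(
        {"T": T, "H": H, "Rf": Rf, "Cc": Cc, "Sd": Sd, "Ws": Ws, "Wd": Wd, "Wg": Wg},
        index=dates,
    )
    weather.index.name = "date"
    return Dataset(weather=weather)


# ---------------------------------------------------------------------------
# ground-truth phenology (independent per-day scan)
# ---------------------------------------------------------------------------

def _truth_start(weather: pd.DataFrame, year: int, truth: TruthParams) -> dt.date:
    f1_year = year - 1 if truth.F1[0] >= 7 else year
    date = monthday_to_date(f1_year, truth.F1)
    end = dt.date(year, 6, 30)
    acc = 0.0
    while date <= end:
        tavg = float(weather.at[pd.Timestamp(date), "T"])
        acc += 1.0 / (1.0 + math.exp(truth.d * (tavg - truth.c)))
        if acc >= truth.M_start:
            return date
        date += dt.timedelta(days=1)
    raise RuntimeError(
        f"year {year}: start forcing only reached {acc:.3f} of required "
        f"{truth.M_start} by 30 June"
    )


def _truth_peak(
    weather: pd.DataFrame, year: int, start: dt.date, truth: TruthParams
) -> dt.date:
    end = dt.date(year, 6, 30)
    date = start + dt.timedelta(days=1)
    # trigger day D_T: first day strictly after the start with T >= T_D
    while date <= end:
        if float(weather.at[pd.Timestamp(date), "T"]) >= truth.T_D:
            break
        date += dt.timedelta(days=1)
    else:
        raise RuntimeError(f"year {year}: peak trigger {truth.T_D} °C never reached")
    if date > end:
        raise RuntimeError(f"year {year}: peak trigger {truth.T_D} °C never reached")
    acc = 0.0
    while date <= end:
        tavg = float(weather.at[pd.Timestamp(date), "T"])
        acc += max(tavg - truth.Th, 0.0)
        if acc >= truth.M_peak:
            return date
        date += dt.timedelta(days=1)
    raise RuntimeError(
        f"year {year}: peak heat only reached {acc:.3f} of required "
        f"{truth.M_peak} by 30 June"
    )


def ground_truth_seasons(
    weather: pd.DataFrame, truth: TruthParams
) -> pd.DataFrame:
    """Ground-truth start*/peak* (day-of-year) for every season year the
    weather covers (onset F1 through 30 June)."""
    first, last = weather.index[0], weather.index[-1]
    rows = []
    for year in range(first.year, last.year + 1):
        f1_year = year - 1 if truth.F1[0] >= 7 else year
        f1_date = pd.Timestamp(monthday_to_date(f1_year, truth.F1))
        if f1_date < first or pd.Timestamp(year, 6, 30) > last:
            continue
        start = _truth_start(weather, year, truth)
        peak = _truth_peak(weather, year, start, truth)
        rows.append(
            {
                "year": year,
                "start_doy": day_of_year(start),
                "peak_doy": day_of_year(peak),
            }
        )
    return pd.DataFrame(rows, columns=["year", "start_doy", "peak_doy"])


# ---------------------------------------------------------------------------
# pollen synthesis
# ---------------------------------------------------------------------------

def _season_kernel(length: int, t_peak: int) -> np.ndarray:
    """Skewed unimodal kernel on days 1..length with maximum 1 at t_peak:
    concave square-root rise, exponential decay with a long right tail."""
    if not 1 <= t_peak <= length:
        raise ValueError(
            f"peak offset {t_peak} outside the {length}-day season"
        )
    t = np.arange(1, length + 1, dtype=float)
    tau = max((length - t_peak) / 4.0, 1.0)
    rise = np.sqrt(t / t_peak)
    decay = np.exp(-(t - t_peak) / tau)
    return np.where(t <= t_peak, rise, decay)


def simulate_pollen(
    weather_ds: Dataset | pd.DataFrame,
    truth: TruthParams,
    noise_cv: float = 0.15,
    seed: int = 0,
    summer_bump: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate daily pollen concentrations driven by the forcing truth.

    Returns ``(pollen, truth_seasons)``: a date-indexed concentration
    frame over the full weather span, and the per-year ground-truth
    start*/peak* days.  With ``noise_cv = 0`` the realised peak equals
    peak* exactly and the 5% cumulative start lands within ~2 days of
    start*.  ``summer_bump`` (fraction of ``peak_magnitude``, off by
    default) adds a small secondary bell around early August.
    """
    weather = weather_ds.weather if isinstance(weather_ds, Dataset) else weather_ds
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be non-negative, got {noise_cv}")
    seasons = ground_truth_seasons(weather, truth)
    if seasons.empty:
        raise ValueError(
            "weather does not cover a single full pollen year "
            "(onset F1 through 30 June)"
        )
    rng = np.random.default_rng(seed)
    conc = pd.Series(0.0, index=weather.index)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    for row in seasons.itertuples():
        start = pd.Timestamp(dt.date(row.year, 1, 1)) + pd.Timedelta(
            days=int(row.start_doy) - 1
        )
        peak = pd.Timestamp(dt.date(row.year, 1, 1)) + pd.Timedelta(
            days=int(row.peak_doy) - 1
        )
        t_peak = (peak - start).days + 1
        kernel = _season_kernel(truth.season_length, t_peak) * truth.peak_magnitude
        days = pd.date_range(start, periods=truth.season_length, freq="D")
        if noise_cv > 0:
            kernel = kernel * rng.lognormal(
                -0.5 * sigma**2, sigma, size=len(kernel)
            )
        conc.loc[days] = np.clip(kernel, 0.0, None)
        if summer_bump > 0:
            bump_days = pd.date_range(
                dt.date(row.year, 7, 20), periods=30, freq="D"
            )
            bump = _season_kernel(30, 10) * truth.peak_magnitude * summer_bump
            if noise_cv > 0:
                bump = bump * rng.lognormal(-0.5 * sigma**2, sigma, size=len(bump))
            conc.loc[bump_days] = np.clip(bump, 0.0, None)
    pollen = conc.to_frame("concentration")
    pollen.index.name = "date"
    return pollen, seasons


def make_dataset(
    config: ClimateConfig | None = None,
    truth: TruthParams | None = None,
    noise_cv: float = 0.15,
) -> tuple[Dataset, pd.DataFrame]:
    """Simulate weather and pollen together.

    Returns the bundled :class:`~pollenseason.core_data.Dataset` and the
    per-year ground-truth season days (columns ``year, start_doy,
    peak_doy``) for use as test oracles.  The pollen seed is derived from
    the climate seed so a single seed fixes the whole dataset.
    """
    config = config or ClimateConfig()
    truth = truth or TruthParams()
    ds = simulate_weather(config)
    pollen, seasons = simulate_pollen(
        ds, truth, noise_cv=noise_cv, seed=config.seed + 1_000_003
    )
    return Dataset(weather=ds.weather, pollen=pollen), seasons
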