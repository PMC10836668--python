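"""Weather-averaging windows and the 80/20 observed/climatology hindcast.

Season predictions are issued from a fixed calendar date (25 Feb by
default) before the season starts, so the weather means that feed the
models must extend past the issue date.  The hindcast stands in for a
short-term forecast: for any day after the issue date, the value used is

    w_obs × (that year's eventual observation) + w_hist × (training-year
    climatological mean for that calendar date)

with default weights 0.8 / 0.2.  Days on or before the issue date use the
observation unchanged.  This is an evaluation device — it emulates the
accuracy of a short-range forecast with historical data — not an
operational forecast feed.

Candidate windows are fixed ``(start month-day, end month-day)`` pairs
applied identically in every year; for the peak-day models the window end
is instead resolved per year to that year's observed season start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_data import (
    WEATHER_VARS,
    DataValidationError,
    MonthDay,
    format_monthday,
    historical_mean_by_monthday,
    monthday_range,
    monthday_to_date,
    parse_monthday,
)

#: Sentinel for "window ends at each year's observed season start".
MPS_START = "mps_start"

#: Default window-search ranges: starts 1 Jan – 25 Feb, ends 1 Mar – 11 Mar.
DEFAULT_START_RANGE: tuple[str, str] = ("01-01", "02-25")
DEFAULT_END_RANGE: tuple[str, str] = ("03-01", "03-11")


@dataclass(frozen=True)
class WindowSpec:
    """An inclusive fixed-calendar averaging window (Jan–Jun frame)."""

    start: MonthDay
    end: MonthDay

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", parse_monthday(self.start))
        object.__setattr__(self, "end", parse_monthday(self.end))
        if not self.start < self.end:
            raise ValueError(
                f"window start {format_monthday(self.start)} must precede "
                f"end {format_monthday(self.end)}"
            )
        if self.end[0] > 6:
            raise ValueError("windows are restricted to the January–June frame")

    def __str__(self) -> str:
        return f"{format_monthday(self.start)}..{format_monthday(self.end)}"


@dataclass(frozen=True)
class BlendConfig:
    """Hindcast blending weights and the prediction issue date."""

    issue_date: MonthDay = (2, 25)
    w_obs: float = 0.8
    w_hist: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "issue_date", parse_monthday(self.issue_date))
        if not (0 <= self.w_obs <= 1 and 0 <= self.w_hist <= 1):
            raise ValueError("blend weights must lie in [0, 1]")
        if abs(self.w_obs + self.w_hist - 1.0) > 1e-9:
            raise ValueError(
                f"blend weights must sum to 1, got {self.w_obs} + {self.w_hist}"
            )


def enumerate_windows(
    start_range: tuple[str | MonthDay, str | MonthDay] = DEFAULT_START_RANGE,
    end_range: tuple[str | MonthDay, str | MonthDay] | str = DEFAULT_END_RANGE,
) -> list[WindowSpec] | list[MonthDay]:
    """Cartesian product of candidate start and end dates.

    With the default ranges this yields the 56 × 11 = 616 windows of the
    start-day search.  Passing ``end_range=MPS_START`` returns the bare
    start dates (56 by default); the per-year window end is then resolved
    downstream to each year's observed season start.
    """
    starts = monthday_range(*start_range)
    if not starts:
        raise ValueError("empty start range")
    if end_range == MPS_START:
        return starts
    ends = monthday_range(*end_range)
    if not ends:
        raise ValueError("empty end range")
    return [WindowSpec(s, e) for s in starts for e in ends]


def blended_value(
    weather: pd.DataFrame,
    year: int,
    monthday: str | MonthDay,
    variable: str,
    blend: BlendConfig,
    training_years: Iterable[int],
) -> float:
    """Weather value for one calendar day under the hindcast blend.

    On or before the issue date the observation passes through unchanged;
    afterwards it is the convex combination of the observation and the
    training-year climatological mean for that calendar date.
    """
    monthday = parse_monthday(monthday)
    ts = pd.Timestamp(monthday_to_date(year, monthday))
    if ts not in weather.index:
        raise DataValidationError(f"no observation for {ts.date()}")
    obs = float(weather.at[ts, variable])
    if monthday <= blend.issue_date:
        return obs
    hist = historical_mean_by_monthday(weather, monthday, variable, training_years)
    return blend.w_obs * obs + blend.w_hist * hist


def blended_daily_frame(
    weather: pd.DataFrame,
    year: int,
    blend: BlendConfig | None,
    training_years: Iterable[int] | None,
    span: tuple[str | MonthDay, str | MonthDay] = ("01-01", "06-30"),
) -> pd.DataFrame:
    """Daily (possibly blended) values for one year over a Jan–Jun span.

    Rows are indexed by month-day key; 29 Feb is dropped.  With
    ``blend=None`` this is just the year's observations.
    """
    monthdays = monthday_range(*span)
    dates = [pd.Timestamp(monthday_to_date(year, md)) for md in monthdays]
    missing = [d for d in dates if d not in weather.index]
    if missing:
        raise DataValidationError(f"no observation for {missing[0].date()}")
    frame = weather.loc[dates, list(WEATHER_VARS)].copy()
    frame.index = pd.MultiIndex.from_tuples(monthdays, names=["month", "day"])
    if blend is not None:
        if training_years is None:
            raise ValueError("blending requires training_years")
        training_years = sorted(set(int(y) for y in training_years))
        post = [md for md in monthdays if md > blend.issue_date]
        if post:
            hist = _climatology(weather, post, training_years)
            frame.loc[post] = (
                blend.w_obs * frame.loc[post].to_numpy() + blend.w_hist * hist
            )
    return frame


def _climatology(
    weather: pd.DataFrame, monthdays: list[MonthDay], years: list[int]
) -> np.ndarray:
    """Training-year mean of every variable on each listed month-day."""
    stack = []
    for year in years:
        dates = [pd.Timestamp(monthday_to_date(year, md)) for md in monthdays]
        missing = [d for d in dates if d not in weather.index]
        if missing:
            raise DataValidationError(
                f"climatology: no observation for {missing[0].date()}"
            )
        stack.append(weather.loc[dates, list(WEATHER_VARS)].to_numpy())
    return np.mean(stack, axis=0)


def window_feature_vector(
    weather: pd.DataFrame,
    year: int,
    window: WindowSpec | tuple[str | MonthDay, str | MonthDay],
    blend: BlendConfig | None = None,
    training_years: Iterable[int] | None = None,
) -> dict[str, float]:
    """Per-variable arithmetic mean over an inclusive window for one year.

    These means are the regressors of the linear season models.  All eight
    variables are averaged with the same rule (including rainfall and wind
    direction, which the models treat linearly).  29 Feb is excluded.
    """
    if isinstance(window, WindowSpec):
        start, end = window.start, window.end
    else:
        # per-year resolved windows may degenerate to a single day
        start, end = parse_monthday(window[0]), parse_monthday(window[1])
        if end < start:
            raise ValueError(
                f"window start {format_monthday(start)} after end {format_monthday(end)}"
            )
    daily = blended_daily_frame(
        weather, year, blend, training_years, span=(start, end)
    )
    return {var: float(daily[var].mean()) for var in WEATHER_VARS}
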