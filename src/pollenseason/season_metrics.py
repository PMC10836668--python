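"""Main-pollen-season (MPS) definitions and the evaluation metric.

The start of the season is defined by a cumulative-percentage criterion:
the first day on which the running sum of daily concentrations (from
1 Jan) reaches a given fraction — 2.5% or 5% — of the annual total, the
two conventions in common aerobiological use.  The peak day is the day of
the year's maximum daily concentration, searched within the spring window
(days 1–181 by default) so that a secondary late-summer rise cannot
capture the argmax.  Model accuracy is summarised as the mean absolute
error (MAE) between predicted and actual season days, in days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import DataValidationError, day_of_year

#: Default peak-day search window (day-of-year, inclusive): January–June.
SPRING_WINDOW: tuple[int, int] = (1, 181)

START_FRACTIONS: tuple[float, float] = (0.025, 0.05)


@dataclass(frozen=True)
class SeasonDates:
    """Observed season landmarks for one calendar year (days-of-year)."""

    year: int
    start_doy_2_5: int
    start_doy_5: int
    peak_doy: int

    def __post_init__(self) -> None:
        if self.start_doy_2_5 > self.start_doy_5:
            raise ValueError(
                f"{self.year}: 2.5% start day {self.start_doy_2_5} after "
                f"5% start day {self.start_doy_5}"
            )

    def start(self, criterion: float) -> int:
        """Start day under a given cumulative criterion (0.025 or 0.05)."""
        if criterion in (0.05, 5):
            return self.start_doy_5
        if criterion in (0.025, 2.5):
            return self.start_doy_2_5
        raise ValueError(f"unknown start criterion {criterion!r}")


def _year_slice(pollen: pd.DataFrame, year: int) -> pd.Series:
    sel = pollen.loc[str(year), "concentration"]
    expected = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    if len(sel) != len(expected):
        raise DataValidationError(f"year {year} not fully covered by pollen series")
    return sel


def annual_start_day(pollen: pd.DataFrame, year: int, fraction: float) -> int:
    """First day-of-year on which the cumulative pollen sum reaches
    ``fraction`` of the full calendar-year total.

    Parameters
    ----------
    pollen
        Date-indexed frame with a ``concentration`` column covering the
        whole calendar year.
    fraction
        Cumulative criterion, conventionally 0.025 or 0.05.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    series = _year_slice(pollen, year)
    total = float(series.sum())
    if total <= 0:
        raise DataValidationError(f"year {year}: annual pollen total is zero")
    cum = series.cumsum()
    when = cum.index[cum.to_numpy() >= fraction * total][0]
    return day_of_year(when)


def annual_peak_day(
    pollen: pd.DataFrame,
    year: int,
    search_window: tuple[int, int] = SPRING_WINDOW,
) -> int:
    """Day-of-year of the maximum concentration within ``search_window``
    (inclusive day-of-year bounds); ties break to the earliest day."""
    lo, hi = search_window
    if lo > hi:
        raise ValueError(f"invalid search window {search_window}")
    series = _year_slice(pollen, year)
    doys = np.array([day_of_year(d) for d in series.index])
    window = series[(doys >= lo) & (doys <= hi)]
    if len(window) == 0:
        raise DataValidationError(f"year {year}: search window {search_window} empty")
    if float(window.max()) <= 0:
        raise DataValidationError(
            f"year {year}: all concentrations zero within days {lo}-{hi}"
        )
    return day_of_year(window.idxmax())  # idxmax: first occurrence


def season_table(
    pollen: pd.DataFrame,
    years: Sequence[int] | None = None,
    search_window: tuple[int, int] = SPRING_WINDOW,
) -> pd.DataFrame:
    """Season landmarks for each year: columns
    ``year, start_doy_2_5, start_doy_5, peak_doy``."""
    if years is None:
        first, last = pollen.index[0], pollen.index[-1]
        years = [
            y for y in range(first.year, last.year + 1)
            if first <= pd.Timestamp(y, 1, 1) and pd.Timestamp(y, 12, 31) <= last
        ]
    rows = []
    for year in years:
        rows.append(
            {
                "year": int(year),
                "start_doy_2_5": annual_start_day(pollen, year, 0.025),
                "start_doy_5": annual_start_day(pollen, year, 0.05),
                "peak_doy": annual_peak_day(pollen, year, search_window),
            }
        )
    return pd.DataFrame(rows, columns=["year", "start_doy_2_5", "start_doy_5", "peak_doy"])


def mean_absolute_error(
    predicted: Sequence[float], actual: Sequence[float]
) -> float:
    """MAE = Σ|PDᵢ − ADᵢ| / n over paired predicted/actual season days."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError(
            f"predicted and actual must be equal-length 1-d sequences, got "
            f"{predicted.shape} vs {actual.shape}"
        )
    if len(predicted) == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean(np.abs(predicted - actual)))
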