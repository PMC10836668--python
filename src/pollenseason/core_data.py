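"""Core domain containers, calendar conventions, and CSV I/O.

Daily weather and airborne-pollen series are held as pandas DataFrames
indexed by calendar date.  Weather frames carry one column per candidate
predictor:

==========  =============================  ==========
column      meaning                        units
==========  =============================  ==========
``T``       daily mean temperature         °C
``H``       relative humidity              %
``Rf``      rainfall                       mm
``Cc``      cloud cover                    %
``Sd``      sunshine duration              hours
``Ws``      wind speed                     km/h
``Wd``      wind direction                 degrees
``Wg``      wind gust                      km/h
==========  =============================  ==========

Regression coefficients are unit-dependent, so these units are part of the
data contract, not a convention that can be changed silently.

Calendar policy
---------------
Days are numbered 1-based within their calendar year (1 Jan = 1; in leap
years 29 Feb = 60 and later days shift by one).  Cross-year alignment —
historical means for a fixed calendar date and fixed weather-averaging
windows — is keyed by ``(month, day)``; 29 Feb is excluded from all
cross-year aggregation so window lengths stay comparable between leap and
common years.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Candidate predictor columns of a weather frame, in CSV schema order.
WEATHER_VARS: tuple[str, ...] = ("T", "H", "Rf", "Cc", "Sd", "Ws", "Wd", "Wg")

#: CSV schema headers.
WEATHER_COLUMNS: tuple[str, ...] = ("date",) + WEATHER_VARS
POLLEN_COLUMNS: tuple[str, ...] = ("date", "concentration")

# per-variable (lower, upper, upper_inclusive); None = unbounded
_BOUNDS: dict[str, tuple[float, float | None, bool]] = {
    "T": (-90.0, 60.0, True),
    "H": (0.0, 100.0, True),
    "Rf": (0.0, None, True),
    "Cc": (0.0, 100.0, True),
    "Sd": (0.0, 24.0, True),
    "Ws": (0.0, None, True),
    "Wd": (0.0, 360.0, False),
    "Wg": (0.0, None, True),
}

# Non-leap reference year for month-day arithmetic.
_REF_YEAR = 2001

MonthDay = tuple[int, int]


class SchemaError(ValueError):
    """A CSV file does not match the declared column schema."""


class DataValidationError(ValueError):
    """A record violates a domain invariant (bounds, gaps, duplicates)."""


# ---------------------------------------------------------------------------
# calendar helpers
# ---------------------------------------------------------------------------

def parse_monthday(value: str | MonthDay) -> MonthDay:
    """Coerce ``"MM-DD"`` strings or ``(month, day)`` pairs to a pair.

    The pair is validated against the non-leap reference calendar, so
    ``(2, 29)`` is rejected (29 Feb is never a cross-year alignment key).
    """
    if isinstance(value, str):
        parts = value.split("-")
        if len(parts) != 2:
            raise ValueError(f"month-day must look like 'MM-DD', got {value!r}")
        month, day = int(parts[0]), int(parts[1])
    else:
        month, day = int(value[0]), int(value[1])
    try:
        dt.date(_REF_YEAR, month, day)
    except ValueError as exc:
        raise ValueError(f"invalid month-day {month:02d}-{day:02d}: {exc}") from None
    return (month, day)


def format_monthday(monthday: str | MonthDay) -> str:
    month, day = parse_monthday(monthday)
    return f"{month:02d}-{day:02d}"


def monthday_of(date: dt.date) -> MonthDay:
    return (date.month, date.day)


def monthday_to_date(year: int, monthday: str | MonthDay) -> dt.date:
    month, day = parse_monthday(monthday)
    return dt.date(year, month, day)


def monthday_range(start: str | MonthDay, end: str | MonthDay) -> list[MonthDay]:
    """Inclusive list of month-days from *start* to *end* (same calendar year,
    29 Feb never included)."""
    start_d = monthday_to_date(_REF_YEAR, start)
    end_d = monthday_to_date(_REF_YEAR, end)
    if end_d < start_d:
        raise ValueError(
            f"month-day range end {format_monthday(end)} precedes start "
            f"{format_monthday(start)}"
        )
    days = pd.date_range(start_d, end_d, freq="D")
    return [(d.month, d.day) for d in days]


def day_of_year(date: dt.date | pd.Timestamp) -> int:
    """1-based ordinal of *date* within its calendar year (1 Jan → 1)."""
    return date.timetuple().tm_yday


def doy_to_date(year: int, doy: int) -> dt.date:
    """Inverse of :func:`day_of_year` for a given year."""
    last = day_of_year(dt.date(year, 12, 31))
    if not 1 <= doy <= last:
        raise ValueError(f"day-of-year {doy} outside [1, {last}] for year {year}")
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_datetime_index(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_index()
    idx = pd.DatetimeIndex(df.index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise DataValidationError(f"duplicate date {dup.date()}")
    df.index = idx.normalize()
    df.index.name = "date"
    return df


def _check_contiguous(index: pd.DatetimeIndex) -> None:
    if len(index) == 0:
        raise DataValidationError("empty series")
    full = pd.date_range(index[0], index[-1], freq="D")
    if len(full) != len(index):
        missing = full.difference(index)
        raise DataValidationError(
            f"daily series has a gap: missing date {missing[0].date()}"
        )


def validate_weather(df: pd.DataFrame, repair_missing: bool = False) -> pd.DataFrame:
    """Validate (and optionally repair) a daily weather frame.

    Missing values are a hard error unless ``repair_missing`` is set, in
    which case interior gaps in each variable are filled by linear
    interpolation in time.
    """
    missing = set(WEATHER_VARS) - set(df.columns)
    extra = set(df.columns) - set(WEATHER_VARS)
    if missing or extra:
        raise SchemaError(
            f"weather columns mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    df = _check_datetime_index(df[list(WEATHER_VARS)].copy())
    _check_contiguous(df.index)
    if df.isna().any().any():
        if repair_missing:
            df = df.interpolate(method="time", limit_area="inside")
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            date = df.index[df[col].isna()][0].date()
            raise DataValidationError(f"missing value for {col} on {date}")
    for var, (lo, hi, hi_incl) in _BOUNDS.items():
        vals = df[var].to_numpy(dtype=float)
        bad = vals < lo
        if hi is not None:
            bad |= (vals > hi) if hi_incl else (vals >= hi)
        if bad.any():
            date = df.index[bad][0].date()
            raise DataValidationError(
                f"value {df.loc[pd.Timestamp(date), var]} out of range for "
                f"{var} on {date}"
            )
    return df


def validate_pollen(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily pollen-concentration frame (grains/m³, ≥ 0)."""
    if set(df.columns) != {"concentration"}:
        raise SchemaError(
            f"pollen columns mismatch: expected ['concentration'], got {sorted(df.columns)}"
        )
    df = _check_datetime_index(df.copy())
    _check_contiguous(df.index)
    vals = df["concentration"].to_numpy(dtype=float)
    if np.isnan(vals).any():
        date = df.index[np.isnan(vals)][0].date()
        raise DataValidationError(f"missing concentration on {date}")
    if (vals < 0).any():
        date = df.index[vals < 0][0].date()
        raise DataValidationError(
            f"negative concentration {df.loc[pd.Timestamp(date), 'concentration']} on {date}"
        )
    return df


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A bundle of co-registered daily weather and pollen series.

    ``weather`` is required; ``pollen`` may be absent (weather-only
    datasets from the simulator).  When both are present they must cover
    the same date span.
    """

    weather: pd.DataFrame
    pollen: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.weather = validate_weather(self.weather)
        if self.pollen is not None:
            self.pollen = validate_pollen(self.pollen)
            if (self.pollen.index[0] != self.weather.index[0]
                    or self.pollen.index[-1] != self.weather.index[-1]):
                raise DataValidationError(
                    "weather and pollen must cover the same date span: "
                    f"weather {self.weather.index[0].date()}..{self.weather.index[-1].date()}, "
                    f"pollen {self.pollen.index[0].date()}..{self.pollen.index[-1].date()}"
                )

    @property
    def years(self) -> list[int]:
        """Calendar years fully covered (1 Jan through 31 Dec) by the weather."""
        first, last = self.weather.index[0], self.weather.index[-1]
        years = []
        for year in range(first.year, last.year + 1):
            if (first <= pd.Timestamp(year, 1, 1)
                    and pd.Timestamp(year, 12, 31) <= last):
                years.append(year)
        return years

    def historical_mean_by_monthday(
        self, monthday: str | MonthDay, variable: str, years: Iterable[int]
    ) -> float:
        return historical_mean_by_monthday(self.weather, monthday, variable, years)


def historical_mean_by_monthday(
    weather: pd.DataFrame,
    monthday: str | MonthDay,
    variable: str,
    years: Iterable[int],
) -> float:
    """Mean of *variable* on a fixed calendar date over the given years.

    This is the climatological component of the 80/20 hindcast blend.
    29 Feb is rejected by policy (it has no cross-year alignment key).
    """
    month, day = parse_monthday(monthday)  # rejects Feb 29
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be non-empty")
    if variable not in WEATHER_VARS:
        raise KeyError(f"unknown weather variable {variable!r}")
    values = []
    for year in years:
        ts = pd.Timestamp(year, month, day)
        if ts not in weather.index:
            raise DataValidationError(
                f"{format_monthday(monthday)} missing in year {year}"
            )
        values.append(float(weather.at[ts, variable]))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_daily_csv(
    path: str | Path, kind: str, repair_missing: bool = False
) -> pd.DataFrame:
    """Read and validate a daily ``weather`` or ``pollen`` CSV.

    Dates are ISO-8601 (``YYYY-MM-DD``); the header must match the schema
    exactly (``date,T,H,Rf,Cc,Sd,Ws,Wd,Wg`` or ``date,concentration``).
    Returns a date-indexed frame sorted ascending.
    """
    if kind not in ("weather", "pollen"):
        raise ValueError(f"kind must be 'weather' or 'pollen', got {kind!r}")
    expected = WEATHER_COLUMNS if kind == "weather" else POLLEN_COLUMNS
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if sorted(header) != sorted(expected) or header[0] != "date":
        raise SchemaError(
            f"{path.name}: expected columns {list(expected)}, got {header}"
        )
    df = pd.read_csv(path)
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except ValueError as exc:
        raise DataValidationError(f"{path.name}: unparseable date: {exc}") from None
    df = df.set_index("date")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            when = bad.index[0].date() if len(bad) else "?"
            raise DataValidationError(
                f"{path.name}: unparseable value in column {col} on {when}"
            ) from None
    if kind == "weather":
        return validate_weather(df, repair_missing=repair_missing)
    return validate_pollen(df)


def write_daily_csv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a validated daily frame in the canonical CSV schema."""
    if kind == "weather":
        df = validate_weather(df)
        cols = list(WEATHER_VARS)
    elif kind == "pollen":
        df = validate_pollen(df)
        cols = ["concentration"]
    else:
        raise ValueError(f"kind must be 'weather' or 'pollen', got {kind!r}")
    out = df[cols].copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)
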