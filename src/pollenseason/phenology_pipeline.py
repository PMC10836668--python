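"""Thermal-forcing phenological models for season start and peak days.

Start-day model.  From an onset date ``F1`` the plant accumulates daily
forcing units through a sigmoid response to daily mean temperature::

    sf = Σ_{t=F1..F} 1 / (1 + exp(d · (tavg_t − c)))

with steepness ``d < 0`` and threshold ``c`` (°C): days well below ``c``
contribute ≈ 0, days well above contribute ≈ 1.  Flowering — the season
start ``F`` — occurs when the accumulated sum reaches a species-specific
requirement ``M``.

Peak-day model.  After the season start, heat accumulates as a clamped
degree-day sum from the first day whose mean temperature reaches a
trigger ``T_D``::

    Heat = Σ_{t=D_T..D} max(Tavg_t − Th, 0)

and the peak ``D`` occurs when the sum reaches its own requirement ``M``
(°C·day).  Contributions are clamped at zero: cold days do not erase
accumulated heat.

Because the species' true thermal requirements are unknown, both models
are calibrated by brute force: every parameter combination on a fixed
grid is scored on the training years, combinations whose mean per-year
forcing is (numerically) zero or whose relative standard deviation across
years exceeds 50% are discarded, and the final combination is the
survivor with the smallest training MAE.  The mean per-year forcing ``M``
of the winning combination becomes the prediction threshold.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    DataValidationError,
    MonthDay,
    day_of_year,
    doy_to_date,
    format_monthday,
    historical_mean_by_monthday,
    monthday_to_date,
    parse_monthday,
)
from .forecast_blend import BlendConfig

#: "non-zero forcing" filter threshold on the mean per-year units.
NONZERO_EPS = 1e-6

#: maximum admissible relative standard deviation, percent.
RSD_MAX = 50.0

#: last day scanned for a threshold crossing (30 June).
SCAN_END: MonthDay = (6, 30)


class NoCrossingError(RuntimeError):
    """The forcing accumulation never reached the requirement M."""


class EmptyGridError(RuntimeError):
    """No grid combination survived the non-zero and RSD filters."""


# ---------------------------------------------------------------------------
# parameter types and grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StartForcingParams:
    """Sigmoid-forcing parameters: onset F1, steepness d (< 0), threshold c."""

    F1: MonthDay
    d: float
    c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "F1", parse_monthday(self.F1))
        if not self.d < 0:
            raise ValueError(f"d must be negative, got {self.d}")
        if not 0 <= self.c <= 40:
            raise ValueError(f"c must lie in [0, 40] °C, got {self.c}")


@dataclass(frozen=True)
class PeakHeatParams:
    """Degree-day parameters: trigger T_D and base temperature Th (°C)."""

    T_D: float
    Th: float

    def __post_init__(self) -> None:
        for name, val in (("T_D", self.T_D), ("Th", self.Th)):
            if not 0 <= val <= 40:
                raise ValueError(f"{name} must lie in [0, 40] °C, got {val}")


@dataclass
class CandidateResult:
    """One calibrated grid combination with its cross-year statistics."""

    params: StartForcingParams | PeakHeatParams
    years: tuple[int, ...]
    per_year_units: np.ndarray
    M: float
    sd: float
    rsd: float
    train_mae: float

    def units_by_year(self) -> dict[int, float]:
        return {y: float(u) for y, u in zip(self.years, self.per_year_units)}


def default_start_grid() -> tuple[list[MonthDay], np.ndarray, np.ndarray]:
    """The full calibration grid for the start model.

    F1 runs over every calendar day from 1 Oct to 28 Feb (151 onsets,
    autumn dates belonging to the year before the season), d over
    −10 … −0.25 in steps of 0.25 (40 values), c over 0 … 40 °C in steps
    of 1 °C (41 values): 247 640 combinations.
    """
    days = pd.date_range("2000-10-01", "2001-02-28", freq="D")
    f1 = [(d.month, d.day) for d in days]
    d_grid = np.round(np.arange(-10.0, 0.0, 0.25), 2)
    c_grid = np.arange(0.0, 41.0, 1.0)
    return f1, d_grid, c_grid


def default_peak_grid() -> tuple[np.ndarray, np.ndarray]:
    """Full peak grid: T_D and Th each 0 … 40 °C in 1 °C steps (41 × 41)."""
    t = np.arange(0.0, 41.0, 1.0)
    return t, t.copy()


def _f1_date(year: int, f1: MonthDay) -> dt.date:
    """Calendar date of onset F1 for the season ending in *year*
    (July–December onsets belong to the preceding year)."""
    return monthday_to_date(year - 1 if f1[0] >= 7 else year, f1)


# ---------------------------------------------------------------------------
# accumulation primitives
# ---------------------------------------------------------------------------

def _temperature_span(
    weather: pd.DataFrame, first: dt.date, last: dt.date
) -> np.ndarray:
    first_ts, last_ts = pd.Timestamp(first), pd.Timestamp(last)
    if first_ts < weather.index[0] or last_ts > weather.index[-1]:
        raise DataValidationError(
            f"weather does not cover {first}..{last} "
            f"(have {weather.index[0].date()}..{weather.index[-1].date()})"
        )
    return weather.loc[first_ts:last_ts, "T"].to_numpy(dtype=float)


def sigmoid_forcing_sum(
    weather: pd.DataFrame,
    year: int,
    params: StartForcingParams,
    until_doy: int,
) -> float:
    """Accumulated sigmoid forcing from F1 through ``until_doy`` inclusive.

    Each day contributes ``1 / (1 + exp(d·(tavg − c))) ∈ (0, 1)``; the sum
    runs across the year boundary when F1 falls in the preceding autumn.
    """
    first = _f1_date(year, params.F1)
    last = doy_to_date(year, until_doy)
    if last < first:
        return 0.0
    temps = _temperature_span(weather, first, last)
    return float(np.sum(1.0 / (1.0 + np.exp(params.d * (temps - params.c)))))


def heat_sum(
    weather: pd.DataFrame,
    year: int,
    params: PeakHeatParams,
    start_doy: int,
    until_doy: int,
) -> float:
    """Clamped degree-day sum between the season start and ``until_doy``.

    Accumulation begins on ``D_T``, the first day strictly after
    ``start_doy`` with mean temperature ≥ ``T_D``; each day from ``D_T``
    contributes ``max(Tavg − Th, 0)``.  Returns 0 when ``D_T`` does not
    occur by ``until_doy``.
    """
    if until_doy < start_doy:
        raise ValueError(f"until_doy {until_doy} precedes start_doy {start_doy}")
    if until_doy == start_doy:
        return 0.0
    first = doy_to_date(year, start_doy) + dt.timedelta(days=1)
    last = doy_to_date(year, until_doy)
    temps = _temperature_span(weather, first, last)
    triggered = np.nonzero(temps >= params.T_D)[0]
    if len(triggered) == 0:
        return 0.0
    return float(np.sum(np.clip(temps[triggered[0]:] - params.Th, 0.0, None)))


# ---------------------------------------------------------------------------
# grid calibration
# ---------------------------------------------------------------------------

def _season_rows(
    seasons: pd.DataFrame, training_years: Iterable[int]
) -> pd.DataFrame:
    years = sorted(set(int(y) for y in training_years))
    if len(years) < 3:
        raise ValueError(f"need at least 3 training years, got {len(years)}")
    rows = seasons.set_index("year").loc[years]
    return rows


def _start_col(criterion: float) -> str:
    if criterion in (0.05, 5):
        return "start_doy_5"
    if criterion in (0.025, 2.5):
        return "start_doy_2_5"
    raise ValueError(f"unknown criterion {criterion!r} (use 5 or 2.5)")


def candidate_grid(
    weather: pd.DataFrame,
    seasons: pd.DataFrame,
    mode: str,
    criterion: float,
    training_years: Iterable[int],
    start_grid: tuple[Sequence, np.ndarray, np.ndarray] | None = None,
    peak_grid: tuple[np.ndarray, np.ndarray] | None = None,
    eps: float = NONZERO_EPS,
    rsd_max: float = RSD_MAX,
) -> list[CandidateResult]:
    """Score every grid combination on the training years and filter.

    For each combination the per-year forcing units are accumulated up to
    the observed start day inclusive (``mode='start'``, sigmoid forcing)
    or from the observed start to the observed peak (``mode='peak'``,
    clamped degree-days).  Combinations with mean units ≤ ``eps`` or
    relative SD above ``rsd_max`` percent are dropped; survivors carry a
    training MAE obtained by predicting each training year with the
    combination's own mean units ``M`` (pure observed weather).  The
    returned list preserves grid order (F1, d, c) / (T_D, Th); a survivor
    whose threshold is never reached in some training year carries an
    infinite training MAE.
    """
    if mode not in ("start", "peak"):
        raise ValueError(f"mode must be 'start' or 'peak', got {mode!r}")
    rows = _season_rows(seasons, training_years)
    years = tuple(int(y) for y in rows.index)
    if mode == "start":
        return _start_candidate_grid(
            weather, rows, years, _start_col(criterion), start_grid, eps, rsd_max
        )
    return _peak_candidate_grid(
        weather, rows, years, _start_col(criterion), peak_grid, eps, rsd_max
    )


def _start_candidate_grid(weather, rows, years, start_col, grid, eps, rsd_max):
    f1_list, d_grid, c_grid = grid if grid is not None else default_start_grid()
    f1_list = [parse_monthday(f) for f in f1_list]
    nf, nd, nc, ny = len(f1_list), len(d_grid), len(c_grid), len(years)

    # Per year: temperatures from the earliest onset through 30 June, with
    # integer offsets for each F1, the observed start (inclusive) and the
    # scan bound.  Offsets double as calendar-day distances for the MAE.
    spans, f1_idx, s_idx, end_idx = [], [], [], []
    for y in years:
        d0 = min(_f1_date(y, f1) for f1 in f1_list)
        d_end = monthday_to_date(y, SCAN_END)
        spans.append(_temperature_span(weather, d0, d_end))
        f1_idx.append(
            np.array([(_f1_date(y, f1) - d0).days for f1 in f1_list])
        )
        s_idx.append((doy_to_date(y, int(rows.loc[y, start_col])) - d0).days)
        end_idx.append((d_end - d0).days)

    units = np.empty((ny, nf, nd, nc))
    pred_err = np.empty((ny, nf, nd, nc))
    for a, d in enumerate(d_grid):
        for b, c in enumerate(c_grid):
            cums = []
            for yi in range(ny):
                terms = 1.0 / (1.0 + np.exp(d * (spans[yi] - c)))
                cum = np.concatenate(([0.0], np.cumsum(terms)))
                cums.append(cum)
                u = cum[s_idx[yi] + 1] - cum[f1_idx[yi]]
                units[yi, :, a, b] = np.clip(u, 0.0, None)
            m = units[:, :, a, b].mean(axis=0)  # (nf,)
            for yi in range(ny):
                cum = cums[yi]
                target = m + cum[f1_idx[yi]]
                j = np.searchsorted(cum[1:], target, side="left")
                err = np.abs(j - s_idx[yi]).astype(float)
                err[j > end_idx[yi]] = np.inf
                pred_err[yi, :, a, b] = err

    M = units.mean(axis=0)
    sd = units.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / M
    mae = pred_err.mean(axis=0)
    keep = (M > eps) & (rsd <= rsd_max)

    out: list[CandidateResult] = []
    for i in range(nf):
        for a in range(nd):
            for b in range(nc):
                if keep[i, a, b]:
                    out.append(
                        CandidateResult(
                            params=StartForcingParams(
                                f1_list[i], float(d_grid[a]), float(c_grid[b])
                            ),
                            years=years,
                            per_year_units=units[:, i, a, b].copy(),
                            M=float(M[i, a, b]),
                            sd=float(sd[i, a, b]),
                            rsd=float(rsd[i, a, b]),
                            train_mae=float(mae[i, a, b]),
                        )
                    )
    if not out:
        raise EmptyGridError(
            "no start-model grid combination survived the non-zero and RSD filters"
        )
    return out


def _peak_candidate_grid(weather, rows, years, start_col, grid, eps, rsd_max):
    td_grid, th_grid = grid if grid is not None else default_peak_grid()
    ntd, nth, ny = len(td_grid), len(th_grid), len(years)

    spans, p_idx, end_idx = [], [], []
    for y in years:
        s = int(rows.loc[y, start_col])
        d0 = doy_to_date(y, s) + dt.timedelta(days=1)
        d_end = monthday_to_date(y, SCAN_END)
        spans.append(_temperature_span(weather, d0, d_end))
        p_idx.append((doy_to_date(y, int(rows.loc[y, "peak_doy"])) - d0).days)
        end_idx.append((d_end - d0).days)

    units = np.zeros((ny, ntd, nth))
    pred_err = np.empty((ny, ntd, nth))
    dt_indices = []
    for yi in range(ny):
        temps = spans[yi]
        dt_idx = np.empty(ntd, dtype=int)
        for k, td in enumerate(td_grid):
            hit = np.nonzero(temps >= td)[0]
            dt_idx[k] = hit[0] if len(hit) else len(temps)
        dt_indices.append(dt_idx)
    for j, th in enumerate(th_grid):
        cums = []
        for yi in range(ny):
            contrib = np.clip(spans[yi] - th, 0.0, None)
            cum = np.concatenate(([0.0], np.cumsum(contrib)))
            cums.append(cum)
            dt_idx = dt_indices[yi]
            active = dt_idx <= p_idx[yi]
            u = np.where(
                active,
                cum[p_idx[yi] + 1] - cum[np.minimum(dt_idx, len(spans[yi]))],
                0.0,
            )
            units[yi, :, j] = u
        m = units[:, :, j].mean(axis=0)  # (ntd,)
        for yi in range(ny):
            cum = cums[yi]
            dt_idx = np.minimum(dt_indices[yi], len(spans[yi]))
            target = m + cum[dt_idx]
            k = np.searchsorted(cum[1:], target, side="left")
            err = np.abs(k - p_idx[yi]).astype(float)
            err[(k > end_idx[yi]) | (dt_indices[yi] >= len(spans[yi]))] = np.inf
            # a zero threshold is reached immediately at D_T itself
            pred_err[yi, :, j] = err

    M = units.mean(axis=0)
    sd = units.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / M
    mae = pred_err.mean(axis=0)
    keep = (M > eps) & (rsd <= rsd_max)

    out: list[CandidateResult] = []
    for i in range(ntd):
        for j in range(nth):
            if keep[i, j]:
                out.append(
                    CandidateResult(
                        params=PeakHeatParams(float(td_grid[i]), float(th_grid[j])),
                        years=years,
                        per_year_units=units[:, i, j].copy(),
                        M=float(M[i, j]),
                        sd=float(sd[i, j]),
                        rsd=float(rsd[i, j]),
                        train_mae=float(mae[i, j]),
                    )
                )
    if not out:
        raise EmptyGridError(
            "no peak-model grid combination survived the non-zero and RSD filters"
        )
    return out


def _param_sort_key(params: StartForcingParams | PeakHeatParams):
    if isinstance(params, StartForcingParams):
        # chronological within the accumulation calendar: Oct..Dec < Jan, Feb
        month, day = params.F1
        return ((month - 10) % 12, day, params.d, params.c)
    return (params.T_D, params.Th)


def select_params(candidates: Sequence[CandidateResult]) -> CandidateResult:
    """Pick the surviving combination with minimal training MAE.

    Ties break by minimal RSD, then by parameter order (F1, d, c) /
    (T_D, Th), so the result is independent of evaluation order.
    """
    if not candidates:
        raise EmptyGridError("empty candidate list")
    best = min(
        candidates,
        key=lambda cand: (cand.train_mae, cand.rsd, _param_sort_key(cand.params)),
    )
    if not math.isfinite(best.train_mae):
        raise NoCrossingError(
            "every surviving combination fails to reach its threshold in "
            "some training year"
        )
    return best


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _blended_temperatures(
    weather: pd.DataFrame,
    dates: pd.DatetimeIndex,
    season_year: int,
    blend: BlendConfig | None,
    training_years: Iterable[int] | None,
) -> np.ndarray:
    temps = weather.loc[dates, "T"].to_numpy(dtype=float).copy()
    if blend is None:
        return temps
    if training_years is None:
        raise ValueError("blending requires training_years")
    issue = pd.Timestamp(monthday_to_date(season_year, blend.issue_date))
    for k, ts in enumerate(dates):
        if ts <= issue:
            continue
        if ts.month == 2 and ts.day == 29:
            continue  # no cross-year key; keep the observation
        hist = historical_mean_by_monthday(
            weather, (ts.month, ts.day), "T", training_years
        )
        temps[k] = blend.w_obs * temps[k] + blend.w_hist * hist
    return temps


def predict_day_phenology(
    params: StartForcingParams | PeakHeatParams,
    M: float,
    weather: pd.DataFrame,
    year: int,
    mode: str,
    start_doy_for_peak: int | None = None,
    blend: BlendConfig | None = None,
    training_years: Iterable[int] | None = None,
) -> int:
    """First day-of-year at which the accumulated forcing reaches ``M``.

    ``mode='start'`` accumulates sigmoid forcing from F1; ``mode='peak'``
    accumulates clamped degree-days from ``D_T`` after the supplied start
    day (observed in training, predicted at forecast time).  Weather after
    the blend's issue date is the 80/20 observed/climatology mix when a
    blend is given.  The scan is bounded at 30 June.
    """
    if M <= 0:
        raise ValueError(f"requirement M must be positive, got {M}")
    last = pd.Timestamp(monthday_to_date(year, SCAN_END))
    if mode == "start":
        if not isinstance(params, StartForcingParams):
            raise TypeError("mode='start' requires StartForcingParams")
        first = pd.Timestamp(_f1_date(year, params.F1))
    elif mode == "peak":
        if not isinstance(params, PeakHeatParams):
            raise TypeError("mode='peak' requires PeakHeatParams")
        if start_doy_for_peak is None:
            raise ValueError("mode='peak' requires start_doy_for_peak")
        first = pd.Timestamp(doy_to_date(year, start_doy_for_peak)) + pd.Timedelta(days=1)
    else:
        raise ValueError(f"mode must be 'start' or 'peak', got {mode!r}")

    dates = pd.date_range(first, last, freq="D")
    if len(dates) == 0:
        raise NoCrossingError(f"year {year}: scan range empty")
    if dates[0] < weather.index[0] or dates[-1] > weather.index[-1]:
        raise DataValidationError(
            f"weather does not cover {dates[0].date()}..{dates[-1].date()}"
        )
    temps = _blended_temperatures(weather, dates, year, blend, training_years)

    if mode == "start":
        contrib = 1.0 / (1.0 + np.exp(params.d * (temps - params.c)))
    else:
        hit = np.nonzero(temps >= params.T_D)[0]
        if len(hit) == 0:
            raise NoCrossingError(
                f"year {year}: trigger temperature {params.T_D} °C never reached"
            )
        contrib = np.zeros(len(temps))
        contrib[hit[0]:] = np.clip(temps[hit[0]:] - params.Th, 0.0, None)

    cum = np.cumsum(contrib)
    crossed = np.nonzero(cum >= M)[0]
    if len(crossed) == 0:
        raise NoCrossingError(
            f"year {year}: accumulation reached {cum[-1]:.3f} of required "
            f"{M:.3f} by {SCAN_END[0]:02d}-{SCAN_END[1]:02d}"
        )
    return day_of_year(dates[crossed[0]])


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

@dataclass
class PhenologyModel:
    """A calibrated phenological model ready for prediction."""

    mode: str
    criterion: float
    params: StartForcingParams | PeakHeatParams
    M: float
    sd: float = float("nan")
    rsd: float = float("nan")
    train_mae: float = float("nan")

    def predict(self, weather, year, **kwargs) -> int:
        return predict_day_phenology(
            self.params, self.M, weather, year, self.mode, **kwargs
        )

    def to_dict(self) -> dict:
        if isinstance(self.params, StartForcingParams):
            p = {
                "F1": format_monthday(self.params.F1),
                "d": self.params.d,
                "c": self.params.c,
            }
        else:
            p = {"T_D": self.params.T_D, "Th": self.params.Th}
        return {
            "model": "phenology",
            "mode": self.mode,
            "criterion": self.criterion,
            "params": p,
            "M": self.M,
            # NaN is not valid JSON; absent diagnostics serialise as null
            "sd": None if math.isnan(self.sd) else self.sd,
            "rsd": None if math.isnan(self.rsd) else self.rsd,
            "train_mae": None if math.isnan(self.train_mae) else self.train_mae,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PhenologyModel":
        p = data["params"]
        if "F1" in p:
            params: StartForcingParams | PeakHeatParams = StartForcingParams(
                parse_monthday(p["F1"]), float(p["d"]), float(p["c"])
            )
        else:
            params = PeakHeatParams(float(p["T_D"]), float(p["Th"]))
        def _num(key):
            value = data.get(key)
            return float("nan") if value is None else float(value)

        return cls(
            mode=data["mode"],
            criterion=float(data["criterion"]),
            params=params,
            M=float(data["M"]),
            sd=_num("sd"),
            rsd=_num("rsd"),
            train_mae=_num("train_mae"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PhenologyModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_phenology(
    weather: pd.DataFrame,
    seasons: pd.DataFrame,
    mode: str,
    criterion: float,
    training_years: Iterable[int],
    start_grid=None,
    peak_grid=None,
) -> PhenologyModel:
    """Grid-calibrate one phenological model and wrap the winner."""
    cands = candidate_grid(
        weather, seasons, mode, criterion, training_years,
        start_grid=start_grid, peak_grid=peak_grid,
    )
    best = select_params(cands)
    return PhenologyModel(
        mode=mode,
        criterion=criterion,
        params=best.params,
        M=best.M,
        sd=best.sd,
        rsd=best.rsd,
        train_mae=best.train_mae,
    )


def load_reference_model(name: str) -> PhenologyModel:
    """Load one of the packaged Islamabad reference parameter sets
    (``start_5``, ``start_2_5``, ``peak_5``, ``peak_2_5``)."""
    fname = f"phenology_islamabad_{name}.json"
    data = json.loads(
        resources.files("pollenseason.fixtures").joinpath(fname).read_text()
    )
    return PhenologyModel.from_dict(data)
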