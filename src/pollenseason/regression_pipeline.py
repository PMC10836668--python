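"""Window-searched stepwise linear regression for season start/peak days.

The response (a season start or peak day-of-year) is regressed on
per-year means of the eight weather variables over a candidate averaging
window, ``y = a + Σ bᵢ·xᵢ``.  For every candidate window the procedure
is:

1. *Variable selection* — greedy forward stepwise: at each step the
   candidate that maximises adjusted R² is added; among the nested models
   the one with the overall highest adjusted R² is kept.  Adjusted R²
   penalises model size, limiting over-fitting on short year series.
2. *Cross-validation* — leave-one-year-out: the selected variables are
   refitted n times leaving one training year out, the held-out year is
   predicted each time, and the final coefficients are the arithmetic
   mean of the n per-fold coefficient vectors.  The model's score is the
   out-of-fold MAE (on day-rounded predictions).

Models whose overall F-test p-value exceeds 0.05 are discarded; among the
survivors the window with the minimum LOOCV MAE wins.  Start-day models
search fixed calendar windows (starts 1 Jan–25 Feb × ends 1 Mar–11 Mar,
616 windows); peak-day models search 56 start dates with the window end
resolved per year to that year's season start, and additionally offer the
start day itself as a ninth candidate feature (the observed start in
training, the predicted start at forecast time).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import (
    WEATHER_VARS,
    MonthDay,
    doy_to_date,
    format_monthday,
    monthday_of,
    parse_monthday,
)
from .forecast_blend import (
    MPS_START,
    DEFAULT_END_RANGE,
    DEFAULT_START_RANGE,
    BlendConfig,
    WindowSpec,
    blended_daily_frame,
    enumerate_windows,
    window_feature_vector,
)

logger = logging.getLogger(__name__)

#: Deterministic tie-break order for stepwise selection.
STEPWISE_ORDER: tuple[str, ...] = ("T", "H", "Cc", "Sd", "Ws", "Wd", "Wg", "Rf")

#: Name of the season-start feature available to peak-day models.
START_FEATURE = "start_day"

#: Overall-model significance gate.
P_GATE = 0.05


class NoAdmissibleModelError(RuntimeError):
    """Every candidate window was discarded by the p ≤ 0.05 gate."""


def round_day(value: float) -> int:
    """Round a predicted day to the nearest integer day, halves away
    from zero."""
    return int(math.floor(value + 0.5))


# ---------------------------------------------------------------------------
# OLS primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OLSFit:
    intercept: float
    coef: tuple[float, ...]
    r2: float
    adj_r2: float
    p_value: float

    def predict(self, x: Sequence[float]) -> float:
        return float(self.intercept + np.dot(self.coef, np.asarray(x, dtype=float)))


def fit_linear(X: pd.DataFrame, y: Sequence[float]) -> OLSFit:
    """Ordinary least squares with adjusted R² and the overall F-test.

    Requires more years than parameters (n > p + 1) and a full-rank,
    non-constant design.  A constant response is a defined degenerate
    case: zero slopes, R² = 0, p-value 1.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError(f"{n} feature rows but {len(y)} responses")
    if n <= p + 1:
        raise ValueError(f"too few years: n={n} must exceed p+1={p + 1}")
    variances = X.to_numpy(dtype=float).var(axis=0)
    if np.any(variances == 0):
        bad = X.columns[np.nonzero(variances == 0)[0][0]]
        raise ValueError(f"feature {bad!r} is constant over the training years")
    if np.var(y) == 0:
        return OLSFit(float(y[0]), tuple(0.0 for _ in range(p)), 0.0, 0.0, 1.0)
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design (collinear features)")
    res = sm.OLS(y, design).fit()
    pval = res.f_pvalue
    if not np.isfinite(pval):
        # perfect fit: zero residual variance makes the F statistic infinite
        pval = 0.0 if res.ssr <= 1e-12 * np.var(y) * n else 1.0
    return OLSFit(
        intercept=float(res.params[0]),
        coef=tuple(float(b) for b in res.params[1:]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        p_value=float(pval),
    )


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    path: list[tuple[tuple[str, ...], OLSFit]]
    variables: tuple[str, ...]
    fit: OLSFit


def _ordered(candidates: Iterable[str]) -> list[str]:
    order = {name: k for k, name in enumerate(STEPWISE_ORDER)}
    fallback = len(order)
    return sorted(candidates, key=lambda v: (order.get(v, fallback), v))


def forward_stepwise(X: pd.DataFrame, y: Sequence[float]) -> StepwiseResult:
    """Greedy forward selection ranked by adjusted R².

    Builds the nested sequence (1, 2, …, p variables), each step adding
    the single candidate that maximises adjusted R² (exact ties break by
    the canonical variable order, T first, Rf last), then returns the
    member of the sequence with the overall highest adjusted R².
    Candidates that cannot be fitted (constant within the training years)
    are skipped.  Growth stops early when no further variable can be
    added within the n > p + 1 limit.
    """
    candidates = _ordered(X.columns)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    n = len(X)
    selected: list[str] = []
    path: list[tuple[tuple[str, ...], OLSFit]] = []
    remaining = list(candidates)
    last_error: Exception | None = None
    while remaining and n > len(selected) + 2:
        best_var, best_fit = None, None
        for var in remaining:
            try:
                fit = fit_linear(X[selected + [var]], y)
            except ValueError as exc:
                last_error = exc
                continue
            if best_fit is None or fit.adj_r2 > best_fit.adj_r2:
                best_var, best_fit = var, fit
        if best_var is None:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        path.append((tuple(selected), best_fit))
    if not path:
        raise ValueError(f"no candidate feature could be fitted: {last_error}")
    variables, fit = max(path, key=lambda entry: entry[1].adj_r2)
    return StepwiseResult(path=path, variables=variables, fit=fit)


def best_subset(X: pd.DataFrame, y: Sequence[float]) -> StepwiseResult:
    """Exhaustive best-subset counterpart of :func:`forward_stepwise`.

    Enumerates every admissible subset of every size and keeps the
    highest adjusted R²; intended for comparison and for verifying that
    greedy selection agrees with the exhaustive search on orthogonal
    designs.
    """
    candidates = _ordered(X.columns)
    n = len(X)
    path = []
    for k in range(1, len(candidates) + 1):
        if n <= k + 1:
            break
        best_entry = None
        for combo in itertools.combinations(candidates, k):
            try:
                fit = fit_linear(X[list(combo)], y)
            except ValueError:
                continue
            if best_entry is None or fit.adj_r2 > best_entry[1].adj_r2:
                best_entry = (combo, fit)
        if best_entry is not None:
            path.append(best_entry)
    if not path:
        raise ValueError("no candidate subset could be fitted")
    variables, fit = max(path, key=lambda entry: entry[1].adj_r2)
    return StepwiseResult(path=path, variables=variables, fit=fit)


# ---------------------------------------------------------------------------
# leave-one-year-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    intercept: float
    coef: dict[str, float]
    mae: float
    fold_errors: dict[int, float]


def loocv_average(
    X: pd.DataFrame, y: Sequence[float], years: Sequence[int]
) -> LoocvResult:
    """Leave-one-year-out refits with coefficient averaging.

    For each training year the model is refitted on the remaining years
    and the held-out year is predicted (rounded to a whole day).  The
    averaged fold coefficients become the final model; the score is the
    mean out-of-fold absolute error, which is invariant to year order.
    """
    y = np.asarray(y, dtype=float)
    years = [int(v) for v in years]
    n = len(years)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 years, got {n}")
    if len(X) != n or len(y) != n:
        raise ValueError("X, y and years must have one row per training year")
    if n < X.shape[1] + 2:
        raise ValueError(
            f"{n} years cannot support {X.shape[1]} features in LOOCV folds"
        )
    intercepts, coefs, errors = [], [], {}
    for i, year in enumerate(years):
        mask = np.arange(n) != i
        # folds need only the coefficient estimates, so an exact fit with
        # zero residual degrees of freedom is acceptable here
        design = np.column_stack(
            [np.ones(n - 1), X.iloc[mask].to_numpy(dtype=float)]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                f"LOOCV fold leaving out {year} failed: rank-deficient design"
            )
        beta, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
        pred = round_day(
            float(beta[0] + X.iloc[i].to_numpy(dtype=float) @ beta[1:])
        )
        errors[year] = abs(pred - y[i])
        intercepts.append(float(beta[0]))
        coefs.append(beta[1:])
    return LoocvResult(
        intercept=float(np.mean(intercepts)),
        coef={
            var: float(b)
            for var, b in zip(X.columns, np.mean(np.asarray(coefs), axis=0))
        },
        mae=float(np.mean(list(errors.values()))),
        fold_errors=errors,
    )


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """A fitted (or loaded) linear season model.

    ``window_end`` is either a fixed month-day or the sentinel
    ``'mps_start'`` for peak models, whose window closes at each year's
    season start.
    """

    response: str
    variables: tuple[str, ...]
    intercept: float
    coef: dict[str, float]
    window_start: MonthDay
    window_end: MonthDay | str
    adj_r2: float = float("nan")
    p_value: float = float("nan")
    loocv_mae: float = float("nan")

    def __post_init__(self) -> None:
        self.window_start = parse_monthday(self.window_start)
        if self.window_end != MPS_START:
            self.window_end = parse_monthday(self.window_end)
        if set(self.variables) != set(self.coef):
            raise ValueError("coefficient keys must match the variable list")

    @property
    def uses_start_feature(self) -> bool:
        return START_FEATURE in self.variables

    def evaluate(self, features: Mapping[str, float]) -> int:
        """a + Σ bᵢ·xᵢ on a realised feature vector, rounded to a day."""
        value = self.intercept + sum(
            self.coef[var] * float(features[var]) for var in self.variables
        )
        return round_day(value)

    def predict(
        self,
        weather: pd.DataFrame,
        year: int,
        blend: BlendConfig | None = None,
        training_years: Iterable[int] | None = None,
        start_doy: int | None = None,
    ) -> int:
        return predict_day(
            self, weather, year,
            blend=blend, training_years=training_years, start_doy=start_doy,
        )

    def to_dict(self) -> dict:
        end = (
            self.window_end
            if self.window_end == MPS_START
            else format_monthday(self.window_end)
        )
        return {
            "model": "linear",
            "response": self.response,
            "window": {"start": format_monthday(self.window_start), "end": end},
            "variables": list(self.variables),
            "intercept": self.intercept,
            "coefficients": dict(self.coef),
            # NaN is not valid JSON; absent diagnostics serialise as null
            "adj_r2": None if math.isnan(self.adj_r2) else self.adj_r2,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "loocv_mae": None if math.isnan(self.loocv_mae) else self.loocv_mae,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinearModel":
        end = data["window"]["end"]

        def _num(key):
            value = data.get(key)
            return float("nan") if value is None else float(value)

        return cls(
            response=data["response"],
            variables=tuple(data["variables"]),
            intercept=float(data["intercept"]),
            coef={k: float(v) for k, v in data["coefficients"].items()},
            window_start=parse_monthday(data["window"]["start"]),
            window_end=end if end == MPS_START else parse_monthday(end),
            adj_r2=_num("adj_r2"),
            p_value=_num("p_value"),
            loocv_mae=_num("loocv_mae"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_reference_model(name: str) -> LinearModel:
    """Load one of the packaged Islamabad reference coefficient sets
    (``start_5``, ``start_2_5``, ``peak_5``, ``peak_2_5``)."""
    fname = f"regression_islamabad_{name}.json"
    data = json.loads(
        resources.files("pollenseason.fixtures").joinpath(fname).read_text()
    )
    return LinearModel.from_dict(data)


# ---------------------------------------------------------------------------
# window search
# ---------------------------------------------------------------------------

@dataclass
class WindowModel:
    """One candidate window's selected and cross-validated model."""

    window_start: MonthDay
    window_end: MonthDay | str
    variables: tuple[str, ...]
    fit: OLSFit
    loocv: LoocvResult
    admissible: bool


@dataclass
class WindowSearchResult:
    models: list[WindowModel]
    best: LinearModel


def _feature_table_fixed(
    weather: pd.DataFrame,
    years: Sequence[int],
    windows: Sequence[WindowSpec],
    blend: BlendConfig | None,
    training_years: Sequence[int],
) -> dict[WindowSpec, pd.DataFrame]:
    """Window-mean features for every (window, year), via prefix sums over
    each year's daily (blended) Jan–Jun values."""
    daily = {
        y: blended_daily_frame(weather, y, blend, training_years) for y in years
    }
    monthdays = list(daily[years[0]].index)
    pos = {md: k for k, md in enumerate(monthdays)}
    prefix = {
        y: np.vstack(
            [np.zeros(len(WEATHER_VARS)), np.cumsum(frame.to_numpy(), axis=0)]
        )
        for y, frame in daily.items()
    }
    out = {}
    for win in windows:
        s, e = pos[win.start], pos[win.end]
        rows = [
            (prefix[y][e + 1] - prefix[y][s]) / (e - s + 1) for y in years
        ]
        out[win] = pd.DataFrame(rows, index=list(years), columns=list(WEATHER_VARS))
    return out


def search_best_window(
    weather: pd.DataFrame,
    seasons: pd.DataFrame,
    mode: str,
    criterion: float,
    training_years: Iterable[int],
    blend: BlendConfig | None = None,
    start_range: tuple = DEFAULT_START_RANGE,
    end_range: tuple | str = DEFAULT_END_RANGE,
    selection: str = "forward",
) -> WindowSearchResult:
    """Enumerate candidate windows and return the minimum-LOOCV-MAE model.

    ``mode='start'`` regresses a start day on fixed calendar windows;
    ``mode='peak'`` regresses the peak day on windows ending at each
    year's observed season start, with the observed start day offered as
    an extra candidate feature.  Windows whose selected model fails the
    overall p ≤ 0.05 gate are recorded but not eligible; if none survive
    a :class:`NoAdmissibleModelError` is raised.
    """
    if mode not in ("start", "peak"):
        raise ValueError(f"mode must be 'start' or 'peak', got {mode!r}")
    if criterion in (5, 0.05):
        start_col, tag = "start_doy_5", "5"
    elif criterion in (2.5, 0.025):
        start_col, tag = "start_doy_2_5", "2_5"
    else:
        raise ValueError(f"unknown criterion {criterion!r} (use 5 or 2.5)")
    years = sorted(set(int(y) for y in training_years))
    if len(years) < 4:
        raise ValueError(f"need at least 4 training years, got {len(years)}")
    rows = seasons.set_index("year").loc[years]
    select = forward_stepwise if selection == "forward" else best_subset

    if mode == "start":
        response = rows[start_col].to_numpy(dtype=float)
        resp_name = f"start_{tag}"
        windows = enumerate_windows(start_range, end_range)
        features = _feature_table_fixed(weather, years, windows, blend, years)
        entries = [(w.start, w.end, features[w]) for w in windows]
    else:
        response = rows["peak_doy"].to_numpy(dtype=float)
        resp_name = f"peak_{tag}"
        starts = enumerate_windows(start_range, MPS_START)
        start_doys = {y: int(rows.loc[y, start_col]) for y in years}
        entries = []
        for s_md in starts:
            per_year = []
            ok = True
            for y in years:
                end_md = monthday_of(doy_to_date(y, start_doys[y]))
                try:
                    vec = window_feature_vector(
                        weather, y, (s_md, end_md), blend=blend, training_years=years
                    )
                except ValueError:
                    ok = False
                    break
                vec[START_FEATURE] = float(start_doys[y])
                per_year.append(vec)
            if not ok:
                continue
            frame = pd.DataFrame(per_year, index=years)
            entries.append((s_md, MPS_START, frame))

    models: list[WindowModel] = []
    best_entry: tuple[float, int] | None = None  # (loocv_mae, index)
    for k, (w_start, w_end, X) in enumerate(entries):
        try:
            step = select(X, response)
            loocv = loocv_average(X[list(step.variables)], response, years)
        except ValueError:
            continue
        admissible = step.fit.p_value <= P_GATE
        models.append(
            WindowModel(w_start, w_end, step.variables, step.fit, loocv, admissible)
        )
        if admissible and (best_entry is None or loocv.mae < best_entry[0]):
            best_entry = (loocv.mae, len(models) - 1)
    if best_entry is None:
        raise NoAdmissibleModelError(
            f"{resp_name}: no window passed the p <= {P_GATE} gate"
        )
    chosen = models[best_entry[1]]
    logger.info(
        "%s: selected window %s..%s, variables %s, adj R2 %.3f, p %.3g, "
        "LOOCV MAE %.2f d (%d/%d admissible windows)",
        resp_name, format_monthday(chosen.window_start),
        chosen.window_end if chosen.window_end == MPS_START
        else format_monthday(chosen.window_end),
        ",".join(chosen.variables), chosen.fit.adj_r2, chosen.fit.p_value,
        chosen.loocv.mae, sum(m.admissible for m in models), len(models),
    )
    best = LinearModel(
        response=resp_name,
        variables=chosen.variables,
        intercept=chosen.loocv.intercept,
        coef=dict(chosen.loocv.coef),
        window_start=chosen.window_start,
        window_end=chosen.window_end,
        adj_r2=chosen.fit.adj_r2,
        p_value=chosen.fit.p_value,
        loocv_mae=chosen.loocv.mae,
    )
    return WindowSearchResult(models=models, best=best)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_day(
    model: LinearModel,
    weather: pd.DataFrame,
    year: int,
    blend: BlendConfig | None = None,
    training_years: Iterable[int] | None = None,
    start_doy: int | None = None,
) -> int:
    """Evaluate a linear season model for one year.

    Peak models (window end ``'mps_start'`` and/or a ``start_day``
    feature) require ``start_doy`` — the observed start in training, the
    predicted start at forecast time.  Weather after the blend's issue
    date is the 80/20 observed/climatology mix when a blend is given.
    """
    if model.window_end == MPS_START or model.uses_start_feature:
        if start_doy is None:
            raise ValueError(f"{model.response}: prediction requires start_doy")
        end_md = monthday_of(doy_to_date(year, int(start_doy)))
    else:
        end_md = model.window_end
    features = window_feature_vector(
        weather, year, (model.window_start, end_md),
        blend=blend, training_years=training_years,
    )
    if model.uses_start_feature:
        features[START_FEATURE] = float(start_doy)
    return model.evaluate(features)
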