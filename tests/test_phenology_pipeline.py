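"""Forcing/heat accumulation, grid calibration with its filters, and
threshold-crossing prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollenseason import phenology_pipeline as ph
from pollenseason.core_data import day_of_year
from pollenseason.forecast_blend import BlendConfig
from pollenseason.season_metrics import season_table
from pollenseason import synthetic_data as sd

from conftest import make_weather


def start_params(F1=(1, 10), d=-0.25, c=15.0):
    return ph.StartForcingParams(F1, d, c)


class TestSigmoidForcingSum:
    def test_midpoint_day_contributes_half(self):
        weather = make_weather("2005-01-10", [15.0])
        value = ph.sigmoid_forcing_sum(weather, 2005, start_params(c=15.0), 10)
        assert value == pytest.approx(0.5)

    def test_scalar_evaluation(self):
        weather = make_weather("2005-01-10", [25.0])
        value = ph.sigmoid_forcing_sum(weather, 2005, start_params(c=15.0), 10)
        assert value == pytest.approx(1.0 / (1.0 + math.exp(-2.5)), rel=1e-6)

    def test_saturated_cold_limit_is_zero(self):
        weather = make_weather("2005-01-10", [-85.0] * 5)
        value = ph.sigmoid_forcing_sum(weather, 2005, start_params(c=15.0), 14)
        assert value < 5e-10

    def test_crosses_the_year_boundary(self):
        temps = np.full(300, 15.0)
        weather = make_weather("2004-11-01", temps)
        params = ph.StartForcingParams((11, 1), -0.25, 15.0)
        # 61 days of Nov-Dec plus 10 days of January, each worth 0.5
        value = ph.sigmoid_forcing_sum(weather, 2005, params, 10)
        assert value == pytest.approx(71 * 0.5)

    def test_coverage_gap_rejected(self):
        weather = make_weather("2005-01-15", [15.0] * 30)
        with pytest.raises(ValueError, match="does not cover"):
            ph.sigmoid_forcing_sum(weather, 2005, start_params(F1=(1, 1)), 20)

    @given(st.integers(12, 40))
    def test_nondecreasing_in_until_doy(self, until):
        weather = make_weather("2005-01-10", np.linspace(5, 20, 60))
        params = start_params()
        a = ph.sigmoid_forcing_sum(weather, 2005, params, until)
        b = ph.sigmoid_forcing_sum(weather, 2005, params, until + 1)
        assert b >= a
        # each daily term lies strictly inside (0, 1)
        assert 0 < b - a < 1

    @given(st.floats(0.5, 5.0))
    def test_strictly_increasing_in_temperature(self, delta):
        weather = make_weather("2005-01-10", np.linspace(5, 20, 40))
        warmer = weather.copy()
        warmer["T"] = warmer["T"] + delta
        params = start_params()
        assert ph.sigmoid_forcing_sum(warmer, 2005, params, 40) > (
            ph.sigmoid_forcing_sum(weather, 2005, params, 40)
        )


class TestHeatSum:
    def test_clamped_sum(self):
        # trigger on day start+1, temps 12, 10, 15 against base 11
        weather = make_weather("2005-03-01", [8.0, 12.0, 10.0, 15.0])
        params = ph.PeakHeatParams(T_D=12.0, Th=11.0)
        value = ph.heat_sum(weather, 2005, params, start_doy=60, until_doy=63)
        assert value == pytest.approx(1.0 + 0.0 + 4.0)

    def test_all_days_below_base_give_zero(self):
        weather = make_weather("2005-03-01", [8.0, 9.0, 10.0, 9.5])
        params = ph.PeakHeatParams(T_D=8.0, Th=11.0)
        assert ph.heat_sum(weather, 2005, params, 60, 63) == 0.0

    def test_zero_base_sums_raw_temperatures(self):
        weather = make_weather("2005-03-01", [0.5, 1.0, 2.0, 3.0])
        params = ph.PeakHeatParams(T_D=1.0, Th=0.0)
        assert ph.heat_sum(weather, 2005, params, 60, 63) == pytest.approx(6.0)

    def test_trigger_never_reached_gives_zero(self):
        weather = make_weather("2005-03-01", [8.0, 9.0, 10.0])
        params = ph.PeakHeatParams(T_D=30.0, Th=0.0)
        assert ph.heat_sum(weather, 2005, params, 60, 62) == 0.0

    @given(st.integers(62, 80))
    def test_nonnegative_and_nondecreasing(self, until):
        weather = make_weather("2005-03-01", np.linspace(8, 22, 40))
        params = ph.PeakHeatParams(T_D=12.0, Th=10.0)
        a = ph.heat_sum(weather, 2005, params, 60, until)
        b = ph.heat_sum(weather, 2005, params, 60, until + 1)
        assert 0 <= a <= b


class TestGrids:
    def test_full_start_grid_cardinality(self):
        f1, d_grid, c_grid = ph.default_start_grid()
        assert len(f1) == 151          # 1 Oct .. 28 Feb
        assert len(d_grid) == 40       # -10.00 .. -0.25 by 0.25
        assert len(c_grid) == 41       # 0 .. 40 by 1
        assert len(f1) * len(d_grid) * len(c_grid) == 247_640
        assert d_grid[0] == -10.0 and d_grid[-1] == -0.25

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ph.StartForcingParams((1, 10), d=0.25, c=15.0)
        with pytest.raises(ValueError):
            ph.StartForcingParams((1, 10), d=-0.25, c=45.0)
        with pytest.raises(ValueError):
            ph.PeakHeatParams(T_D=-1.0, Th=10.0)


@pytest.fixture(scope="module")
def toy():
    """Three noiseless synthetic seasons for mini-grid calibration."""
    ds, _ = sd.make_dataset(
        sd.ClimateConfig(n_years=3, start_year=2005, seed=11), noise_cv=0.0
    )
    return ds.weather, season_table(ds.pollen)


class TestCandidateGridOracle:
    """candidate_grid + select_params must agree exactly with a plain
    brute-force enumeration built on the scalar accumulation ops."""

    def _oracle_start(self, weather, seasons, f1_list, d_grid, c_grid, years):
        rows = seasons.set_index("year")
        results = []
        for f1 in f1_list:
            for d in d_grid:
                for c in c_grid:
                    params = ph.StartForcingParams(f1, float(d), float(c))
                    units = [
                        ph.sigmoid_forcing_sum(
                            weather, y, params, int(rows.loc[y, "start_doy_5"])
                        )
                        for y in years
                    ]
                    m = float(np.mean(units))
                    s = float(np.std(units, ddof=1))
                    rsd = 100.0 * s / m if m > 0 else float("inf")
                    if m <= ph.NONZERO_EPS or rsd > ph.RSD_MAX:
                        continue
                    errs = []
                    for y in years:
                        try:
                            pred = ph.predict_day_phenology(
                                params, m, weather, y, "start"
                            )
                            errs.append(abs(pred - int(rows.loc[y, "start_doy_5"])))
                        except ph.NoCrossingError:
                            errs.append(float("inf"))
                    results.append((params, m, s, rsd, float(np.mean(errs))))
        return results

    def test_start_mode_matches_bruteforce(self, toy):
        weather, seasons = toy
        years = [2005, 2006, 2007]
        f1_list = [(1, 20), (1, 31), (2, 10)]
        d_grid = np.array([-0.5, -0.25])
        c_grid = np.array([14.0, 16.0])
        cands = ph.candidate_grid(
            weather, seasons, "start", 5, years,
            start_grid=(f1_list, d_grid, c_grid),
        )
        oracle = self._oracle_start(weather, seasons, f1_list, d_grid, c_grid, years)
        assert len(cands) == len(oracle)
        for cand, (params, m, s, rsd, mae) in zip(cands, oracle):
            assert cand.params == params
            assert cand.M == pytest.approx(m, rel=1e-12)
            assert cand.sd == pytest.approx(s, rel=1e-9)
            assert cand.rsd == pytest.approx(rsd, rel=1e-9)
            assert cand.train_mae == pytest.approx(mae)
        best = ph.select_params(cands)
        best_oracle = min(oracle, key=lambda r: (r[4], r[3]))
        assert best.params == best_oracle[0]

    def test_peak_mode_matches_bruteforce(self, toy):
        weather, seasons = toy
        years = [2005, 2006, 2007]
        td_grid = np.array([14.0, 16.0])
        th_grid = np.array([9.0, 11.0, 13.0])
        cands = ph.candidate_grid(
            weather, seasons, "peak", 5, years, peak_grid=(td_grid, th_grid)
        )
        rows = seasons.set_index("year")
        oracle = []
        for td in td_grid:
            for th in th_grid:
                params = ph.PeakHeatParams(float(td), float(th))
                units = [
                    ph.heat_sum(
                        weather, y, params,
                        int(rows.loc[y, "start_doy_5"]),
                        int(rows.loc[y, "peak_doy"]),
                    )
                    for y in years
                ]
                m = float(np.mean(units))
                s = float(np.std(units, ddof=1))
                rsd = 100.0 * s / m if m > 0 else float("inf")
                if m <= ph.NONZERO_EPS or rsd > ph.RSD_MAX:
                    continue
                oracle.append((params, m, rsd))
        assert len(cands) == len(oracle)
        for cand, (params, m, rsd) in zip(cands, oracle):
            assert cand.params == params
            assert cand.M == pytest.approx(m, rel=1e-12)
            assert cand.rsd == pytest.approx(rsd, rel=1e-9)

    def test_rsd_filter_drops_inconsistent_candidates(self, toy):
        """Per-year units of [10, 30] have RSD ≈ 70.7% and must be absent."""
        units = np.array([10.0, 30.0])
        rsd = 100 * units.std(ddof=1) / units.mean()
        assert rsd == pytest.approx(70.71, abs=0.01)
        weather, seasons = toy
        cands = ph.candidate_grid(
            weather, seasons, "start", 5, [2005, 2006, 2007],
            start_grid=([(1, 31)], np.array([-0.25]), np.arange(0.0, 41.0, 1.0)),
        )
        assert all(c.rsd <= ph.RSD_MAX for c in cands)
        assert all(c.M > ph.NONZERO_EPS for c in cands)

    def test_cold_threshold_filtered_out_entirely(self, toy):
        weather, seasons = toy
        with pytest.raises(ph.EmptyGridError):
            ph.candidate_grid(
                weather, seasons, "start", 5, [2005, 2006, 2007],
                start_grid=([(2, 20)], np.array([-10.0]), np.array([40.0])),
            )


class TestSelectParams:
    def _cand(self, params, mae, rsd):
        return ph.CandidateResult(
            params=params, years=(2004, 2005, 2006),
            per_year_units=np.ones(3), M=1.0, sd=0.1, rsd=rsd, train_mae=mae,
        )

    def test_single_survivor_returned(self):
        cand = self._cand(ph.PeakHeatParams(15.0, 10.0), 2.0, 10.0)
        assert ph.select_params([cand]) is cand

    def test_minimum_mae_wins(self):
        a = self._cand(ph.PeakHeatParams(15.0, 10.0), 2.0, 20.0)
        b = self._cand(ph.PeakHeatParams(16.0, 11.0), 3.0, 5.0)
        assert ph.select_params([a, b]) is a

    def test_mae_tie_broken_by_rsd_then_params(self):
        a = self._cand(ph.PeakHeatParams(16.0, 11.0), 2.0, 20.0)
        b = self._cand(ph.PeakHeatParams(15.0, 10.0), 2.0, 10.0)
        assert ph.select_params([a, b]) is b
        c = self._cand(ph.PeakHeatParams(14.0, 12.0), 2.0, 10.0)
        assert ph.select_params([a, b, c]) is c  # lexicographic (T_D, Th)

    def test_empty_list_rejected(self):
        with pytest.raises(ph.EmptyGridError):
            ph.select_params([])


class TestPredictDayPhenology:
    def test_constant_temperature_closed_form(self):
        """With a constant daily term s and M = 10·s the crossing is the
        10th day counted from F1 inclusive."""
        weather = make_weather("2005-01-01", np.full(181, 15.0))
        params = start_params(F1=(1, 10), c=15.0)  # each day contributes 0.5
        day = ph.predict_day_phenology(params, 10 * 0.5, weather, 2005, "start")
        assert day == day_of_year(pd.Timestamp("2005-01-19"))

    def test_unreachable_requirement_raises(self):
        weather = make_weather("2005-01-01", np.full(181, 15.0))
        with pytest.raises(ph.NoCrossingError):
            ph.predict_day_phenology(
                start_params(), 1e6, weather, 2005, "start"
            )

    def test_pure_observation_blend_is_identity(self, noiseless, train_years):
        ds, _, _ = noiseless
        params = start_params(F1=(1, 31))
        plain = ph.predict_day_phenology(params, 14.7, ds.weather, 2017, "start")
        blended = ph.predict_day_phenology(
            params, 14.7, ds.weather, 2017, "start",
            blend=BlendConfig(w_obs=1.0, w_hist=0.0), training_years=train_years,
        )
        assert plain == blended

    def test_peak_mode_requires_start_day(self, noiseless):
        ds, _, _ = noiseless
        with pytest.raises(ValueError, match="start_doy_for_peak"):
            ph.predict_day_phenology(
                ph.PeakHeatParams(16.0, 11.0), 34.0, ds.weather, 2017, "peak"
            )

    def test_warming_never_delays_prediction(self, noiseless):
        ds, _, _ = noiseless
        params = start_params(F1=(1, 31))
        warmer = ds.weather.copy()
        warmer["T"] = warmer["T"] + 2.0
        for year in (2016, 2017, 2018):
            assert ph.predict_day_phenology(
                params, 14.7, warmer, year, "start"
            ) <= ph.predict_day_phenology(params, 14.7, ds.weather, year, "start")

    def test_reference_parameter_sets_load_and_predict(self, noiseless, train_years):
        ds, _, _ = noiseless
        start_model = ph.load_reference_model("start_5")
        assert start_model.params.c == 15.5 and start_model.M == 14.70
        day = start_model.predict(ds.weather, 2016)
        assert 32 <= day <= 181
        peak_model = ph.load_reference_model("peak_5")
        peak = peak_model.predict(ds.weather, 2016, start_doy_for_peak=day)
        assert day < peak <= 181

    def test_model_roundtrip(self, tmp_path, toy):
        weather, seasons = toy
        model = ph.fit_phenology(
            weather, seasons, "peak", 5, [2005, 2006, 2007],
            peak_grid=(np.arange(10.0, 20.0), np.arange(8.0, 14.0)),
        )
        model.save(tmp_path / "m.json")
        again = ph.PhenologyModel.load(tmp_path / "m.json")
        assert again.to_dict() == model.to_dict()
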