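"""SER, thermal time, plateau detection and phase-timing extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import stemtherm as st
from stemtherm.traits import (
    accumulate_gdd,
    build_interval_table,
    compute_ser,
    derive_durations,
    detect_final_height,
    extract_phase_timings,
    interval_temperature,
)


def _series(dates, heights_m):
    return pd.DataFrame({"date": pd.to_datetime(dates), "height_m": heights_m})


def _const_temp(mean, start="2017-01-01", days=250, year=2017):
    cfg = st.TemperatureConfig(annual_mean=mean, amplitude=0.0, noise_sd=0.0)
    end = pd.Timestamp(start) + pd.Timedelta(days=days)
    return st.simulate_temperature(year, start, end, cfg)


class TestComputeSer:
    def test_arithmetic_in_mm_per_day(self):
        rec = compute_ser(_series(["2017-05-01", "2017-05-04"], [0.200, 0.260]))
        assert rec["delta_t"].iloc[0] == 3.0
        assert rec["ser"].iloc[0] == pytest.approx(20.0)

    def test_flat_series_zero(self):
        rec = compute_ser(
            _series(["2017-05-01", "2017-05-04", "2017-05-08"], [0.4, 0.4, 0.4])
        )
        assert np.allclose(rec["ser"], 0.0)

    def test_n_minus_one_records(self):
        rec = compute_ser(
            _series(pd.date_range("2017-05-01", periods=7, freq="3D"), np.linspace(0.2, 0.5, 7))
        )
        assert len(rec) == 6

    def test_duplicate_dates_error_names_plot(self):
        s = _series(["2017-05-01", "2017-05-01"], [0.2, 0.3])
        with pytest.raises(ValueError, match="plot42"):
            compute_ser(s, plot_id="plot42")

    def test_noiseless_constant_rate_matches_simulator(self, noiseless_result):
        # on a noiseless plot every interior SER equals the configured daily
        # rate implied by the genotype's slope/vigour and the interval mean T
        trial = noiseless_result.trial
        truth = trial.truth_plots.set_index("plot_id")
        iv = build_interval_table(trial.heights, trial.temperatures)
        one = iv[iv["plot_id"] == iv["plot_id"].iloc[0]]
        t = truth.loc[one["plot_id"].iloc[0]]
        expected = t["true_vigour"] + t["true_slope"] * (one["tmean_interval"] - 12.0)
        interior = (one["ser"] > 0).to_numpy()
        interior[np.r_[True, ~interior[:-1]] | np.r_[~interior[1:], True]] = False
        assert np.allclose(one["ser"].to_numpy()[interior], expected.to_numpy()[interior])


class TestIntervalTemperature:
    def test_constant(self):
        temp = _const_temp(15.0)
        rec = compute_ser(_series(["2017-05-01", "2017-05-04"], [0.2, 0.26]))
        assert interval_temperature(rec, temp)[0] == pytest.approx(15.0)

    def test_mean_of_days(self):
        cfg = st.TemperatureConfig(annual_mean=0, amplitude=0, noise_sd=0)
        temp = st.simulate_temperature(2017, "2017-05-01", "2017-05-04", cfg)
        temp.tmean[:] = [99.0, 10.0, 12.0, 14.0]  # half-open: sowing day excluded
        rec = compute_ser(_series(["2017-05-01", "2017-05-04"], [0.2, 0.26]))
        assert interval_temperature(rec, temp)[0] == pytest.approx(12.0)

    def test_missing_days_listed(self):
        temp = _const_temp(15.0, days=2)
        rec = compute_ser(_series(["2017-01-01", "2017-01-10"], [0.2, 0.3]))
        with pytest.raises(ValueError, match="missing days"):
            interval_temperature(rec, temp)

    def test_vectorized_table_matches_loop_oracle(self):
        trial = st.simulate_trial(
            st.ScenarioConfig(genotype=st.GenotypeConfig(n_genotypes=4), seed=2)
        )
        iv = build_interval_table(trial.heights, trial.temperatures)
        for year in (2015, 2017):
            sub = iv[iv["year"] == year].head(40)
            oracle = interval_temperature(sub, trial.temperatures[year])
            assert np.allclose(sub["tmean_interval"], oracle)


class TestAccumulateGdd:
    def _temp_from_values(self, values, start="2017-03-01"):
        cfg = st.TemperatureConfig(annual_mean=0, amplitude=0, noise_sd=0)
        end = pd.Timestamp(start) + pd.Timedelta(days=len(values) - 1)
        t = st.simulate_temperature(2017, start, end, cfg)
        t.tmean[:] = values
        return t

    def test_base_zero_cumsum(self):
        t = self._temp_from_values([0.0, 10.0, 12.0, 8.0])
        g = accumulate_gdd(t, base=0.0)
        assert list(g) == [0.0, 10.0, 22.0, 30.0]

    def test_negative_day_contributes_zero(self):
        t = self._temp_from_values([0.0, 10.0, -2.0, 8.0])
        g = accumulate_gdd(t, base=0.0)
        assert list(g) == [0.0, 10.0, 10.0, 18.0]

    def test_base_five(self):
        t = self._temp_from_values([0.0, 10.0, 12.0, 8.0])
        g = accumulate_gdd(t, base=5.0)
        assert list(g) == [0.0, 5.0, 12.0, 15.0]

    def test_zero_at_sowing_and_non_decreasing(self):
        t = _const_temp(9.0)
        g = accumulate_gdd(t)
        assert g.iloc[0] == 0.0
        assert (np.diff(g) >= 0).all()


class TestFinalHeight:
    def test_constructed_plateau(self):
        h = [0.2, 0.3, 0.4, 0.5, 0.501, 0.502, 0.502]
        res = detect_final_height(
            _series(pd.date_range("2017-05-01", periods=7, freq="4D"), h)
        )
        assert not res.flagged
        assert res.fh_m == pytest.approx(0.502)

    def test_monotone_series_flagged_fallback(self):
        h = np.linspace(0.2, 0.8, 8)
        res = detect_final_height(
            _series(pd.date_range("2017-05-01", periods=8, freq="4D"), h)
        )
        assert res.flagged
        assert res.fh_m == pytest.approx(0.8)

    def test_leading_baseline_not_mistaken_for_plateau(self):
        # flat before growth starts, then growth, then the real plateau
        h = [0.1, 0.1, 0.1, 0.3, 0.5, 0.7, 0.701, 0.701, 0.702]
        res = detect_final_height(
            _series(pd.date_range("2017-05-01", periods=9, freq="4D"), h)
        )
        assert not res.flagged
        assert res.fh_m == pytest.approx(0.702)

    def test_noiseless_plots_exact(self, noiseless_result):
        tp = noiseless_result.traits_plot.set_index("plot_id")
        truth = noiseless_result.trial.truth_plots.set_index("plot_id")
        joined = tp.join(truth[["true_fh_m"]])
        assert np.allclose(joined["fh_m"], joined["true_fh_m"], rtol=1e-12)

    @given(
        tol_lo=hst.floats(min_value=0.5, max_value=10.0),
        tol_hi=hst.floats(min_value=0.5, max_value=10.0),
        seed=hst.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=40, deadline=None)
    def test_raising_tolerance_never_delays_plateau(self, tol_lo, tol_hi, seed):
        if tol_lo > tol_hi:
            tol_lo, tol_hi = tol_hi, tol_lo
        r = np.random.default_rng(seed)
        h = np.cumsum(np.maximum(r.normal(8, 6, 15), 0)) / 1000.0 + 0.2
        s = _series(pd.date_range("2017-05-01", periods=15, freq="4D"), h)
        lo = detect_final_height(s, tol_mm=tol_lo)
        hi = detect_final_height(s, tol_mm=tol_hi)
        assert hi.plateau_date <= lo.plateau_date


class TestPhaseTimings:
    def _linear_thermal_rise(self):
        """Height rising linearly in thermal time from 0 at GDD 500 to fh at
        GDD 1500, on a constant 10 degC/day series (GDD = 10 * day)."""
        temp = _const_temp(10.0, start="2017-01-01", days=200)
        gdd = accumulate_gdd(temp)
        days = np.arange(45, 160, 5)
        fh = 0.9
        heights = np.clip((10.0 * days - 500.0) / 1000.0, 0, 1) * fh
        s = _series(temp.dates[days], heights)
        return s, gdd, fh

    def test_linear_interpolation_crossings(self):
        s, gdd, fh = self._linear_thermal_rise()
        gdd15, gdd95 = extract_phase_timings(s, fh, gdd)
        assert gdd15 == pytest.approx(650.0, abs=1e-6)
        assert gdd95 == pytest.approx(1450.0, abs=1e-6)

    def test_duration_identities(self):
        s, gdd, fh = self._linear_thermal_rise()
        gdd15, gdd95 = extract_phase_timings(s, fh, gdd)
        gdd_se, time_se = derive_durations(gdd15, gdd95, gdd)
        assert gdd_se == pytest.approx(800.0, abs=1e-6)
        # constant 10 degC/day accumulation: time_se = gdd_se / 10
        assert time_se == pytest.approx(80.0, abs=1e-6)

    def test_phase_incomplete_raises(self):
        s = _series(
            pd.date_range("2017-05-01", periods=6, freq="4D"),
            np.linspace(0.1, 0.5, 6),
        )
        temp = _const_temp(10.0, start="2017-04-01", days=100)
        with pytest.raises(ValueError, match="phase incomplete"):
            extract_phase_timings(s, 1.0, accumulate_gdd(temp))

    def test_inverted_crossings_raise(self):
        temp = _const_temp(10.0)
        with pytest.raises(ValueError, match="smaller"):
            derive_durations(900.0, 800.0, accumulate_gdd(temp))

    def test_noiseless_crossings_near_truth(self, noiseless_result):
        # one observation interval in thermal time bounds the extraction error
        tp = noiseless_result.traits_plot.set_index("plot_id")
        truth = noiseless_result.trial.truth_plots.set_index("plot_id")
        j = tp.join(truth[["true_gdd15", "true_gdd95"]]).dropna()
        step = 4 * 18.0  # max interval days x max daily GDD in the window
        assert (np.abs(j["gdd15"] - j["true_gdd15"]) < step).all()
        assert (np.abs(j["gdd95"] - j["true_gdd95"]) < step).all()
        assert (j["gdd15"] < j["gdd95"]).all()
        assert np.allclose(j["gdd_se"], j["gdd95"] - j["gdd15"])


class TestSerCumsumIdentity:
    @given(seed=hst.integers(min_value=0, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_discrete_fundamental_theorem(self, seed):
        # integrating SER over intervals reproduces the height differences
        r = np.random.default_rng(seed)
        n = 12
        dates = pd.Timestamp("2017-05-01") + pd.to_timedelta(
            np.cumsum(np.r_[0, r.integers(1, 6, n - 1)]), unit="D"
        )
        h = np.cumsum(r.uniform(0, 0.05, n)) + 0.2
        rec = compute_ser(_series(dates, h))
        rebuilt = h[0] + np.cumsum(rec["ser"] * rec["delta_t"]) / 1000.0
        assert np.allclose(rebuilt, h[1:])
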