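"""Chamber flux computation, unit conversion, Q10 and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from stemflux import (ChamberSpec, ConcentrationSeries, DegenerateSeriesError,
                      chamber_flux, convert_flux_units, filter_flux_table,
                      fit_concentration_slope, generate_chamber_closures,
                      hourly_to_daily, iqr_outlier_filter, process_closures,
                      q10_standardize)


def series_from_slope(slope, chamber, noise=None, c0=400.0, **kw):
    t = np.arange(0.0, chamber.closure_duration_s + 0.5, 1.0)
    co2 = c0 + slope * t + (noise if noise is not None else 0.0)
    return ConcentrationSeries(t, co2, **kw)


class TestSlopeFit:
    def test_exact_line_recovered(self, chamber):
        fit = fit_concentration_slope(series_from_slope(0.1, chamber), chamber)
        assert fit.slope == pytest.approx(0.1)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_series_zero_slope_r2_zero(self, chamber):
        fit = fit_concentration_slope(series_from_slope(0.0, chamber), chamber)
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_noisy_slope_matches_closed_form_ols(self, chamber, rng):
        noise = rng.normal(0.0, 0.5, 181)
        series = series_from_slope(0.1, chamber, noise=noise)
        fit = fit_concentration_slope(series, chamber)
        # independent closed-form OLS on the same post-dead-band points
        mask = series.time_s >= 90.0
        t, y = series.time_s[mask], series.co2_umol_mol[mask]
        beta = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert fit.slope == pytest.approx(beta, rel=1e-12)
        assert abs(fit.slope - 0.1) < 0.01

    def test_dead_band_points_are_ignored(self, chamber):
        t = np.arange(0.0, 181.0)
        co2 = 400.0 + 0.1 * t
        co2[t < 90] = 400.0  # corrupt the mixing phase
        fit = fit_concentration_slope(ConcentrationSeries(t, co2), chamber)
        assert fit.slope == pytest.approx(0.1)

    def test_too_few_points_after_dead_band(self, chamber):
        s = ConcentrationSeries(np.array([0.0, 50.0, 95.0]),
                                np.array([400.0, 405.0, 410.0]))
        with pytest.raises(DegenerateSeriesError):
            fit_concentration_slope(s, chamber)

    def test_time_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ConcentrationSeries(np.array([0.0, 2.0, 1.0]),
                                np.array([400.0, 401.0, 402.0]))


class TestChamberFlux:
    def test_flux_equation_worked_example(self, chamber):
        series = series_from_slope(0.1, chamber, pressure_kpa=101.325,
                                   h2o_mmol_mol=0.0, temp_c=25.0)
        fit = fit_concentration_slope(series, chamber)
        assert chamber_flux(fit, series, chamber) == pytest.approx(2.316, abs=5e-4)

    def test_zero_slope_zero_flux(self, chamber):
        series = series_from_slope(0.0, chamber)
        fit = fit_concentration_slope(series, chamber)
        assert chamber_flux(fit, series, chamber) == 0.0

    def test_water_vapour_dilution_factor(self, chamber):
        dry = series_from_slope(0.1, chamber, h2o_mmol_mol=0.0)
        wet = series_from_slope(0.1, chamber, h2o_mmol_mol=20.0)
        fit = fit_concentration_slope(dry, chamber)
        f_dry = chamber_flux(fit, dry, chamber, mode="closed_system")
        f_wet = chamber_flux(fit, wet, chamber, mode="closed_system")
        assert f_wet == pytest.approx(0.98 * f_dry, rel=1e-12)

    def test_ideal_gas_ignores_water(self, chamber):
        wet = series_from_slope(0.1, chamber, h2o_mmol_mol=20.0)
        dry = series_from_slope(0.1, chamber, h2o_mmol_mol=0.0)
        fit = fit_concentration_slope(wet, chamber)
        assert (chamber_flux(fit, wet, chamber, mode="ideal_gas")
                == pytest.approx(chamber_flux(fit, dry, chamber,
                                              mode="closed_system"), rel=1e-12))

    @given(scale=st.floats(0.1, 10.0))
    def test_linear_in_slope(self, scale):
        chamber = ChamberSpec(5000.0, 88.25)
        s = series_from_slope(0.05, chamber)
        fit1 = fit_concentration_slope(s, chamber)
        fit2 = type(fit1)(slope=scale * fit1.slope, intercept=fit1.intercept,
                          r2=fit1.r2, n=fit1.n)
        assert chamber_flux(fit2, s, chamber) == pytest.approx(
            scale * chamber_flux(fit1, s, chamber), rel=1e-12)

    def test_bad_mode_rejected(self, chamber):
        s = series_from_slope(0.1, chamber)
        fit = fit_concentration_slope(s, chamber)
        with pytest.raises(ValueError):
            chamber_flux(fit, s, chamber, mode="exponential")


@pytest.mark.parametrize("flux_in, expected", [
    (1.0, 43.2396),            # dimensional analysis: 12.011 ug C/umol * 3600/1000
    (0.0, 0.0),
    (2.316, 100.1429),
])
def test_convert_flux_units(flux_in, expected):
    assert convert_flux_units(flux_in) == pytest.approx(expected, abs=5e-4)


def test_hourly_to_daily():
    assert hourly_to_daily(1000.0) == pytest.approx(24.0)


class TestQ10:
    @pytest.mark.parametrize("ea, t_meas, t_ref, q10, expected", [
        (123.4, 25.0, 25.0, 2.0, 123.4),       # same temperature: unchanged
        (100.0, 35.0, 25.0, 2.0, 50.0),        # one full decade
        (100.0, 30.24, 25.0, 2.0, 69.544),     # 100 * 2^(-0.524)
    ])
    def test_standardization(self, ea, t_meas, t_ref, q10, expected):
        assert q10_standardize(ea, t_meas, t_ref, q10) == pytest.approx(
            expected, abs=5e-3)

    @given(ea=st.floats(0.1, 500.0), t=st.floats(15.0, 40.0))
    def test_invertible(self, ea, t):
        out = q10_standardize(q10_standardize(ea, t, 25.0, 2.0), 25.0, t, 2.0)
        assert out == pytest.approx(ea, rel=1e-12)

    def test_nonpositive_q10_rejected(self):
        with pytest.raises(ValueError):
            q10_standardize(100.0, 30.0, 25.0, q10=0.0)


class TestIQRFilter:
    def test_single_high_outlier(self):
        res = iqr_outlier_filter([1.0, 2.0, 3.0, 4.0, 100.0])
        # linear-interpolation quartiles: Q1=2, Q3=4, upper fence 7
        assert list(res.removed_indices) == [4]
        assert list(res.kept) == [1.0, 2.0, 3.0, 4.0]

    def test_all_equal_nothing_removed(self):
        res = iqr_outlier_filter([5.0] * 6)
        assert res.removed_indices.size == 0

    def test_symmetric_fences(self):
        res = iqr_outlier_filter([-10.0, -1.0, 0.0, 1.0, 10.0])
        assert sorted(res.removed_indices) == [0, 4]

    def test_small_group_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="smaller than 4"):
            res = iqr_outlier_filter([1.0, 2.0, 100.0])
        assert res.warned and res.removed_indices.size == 0

    @given(st.lists(st.floats(-100.0, 100.0), min_size=4, max_size=30))
    def test_refiltering_only_removes(self, values):
        # the 1.5*IQR rule is a single-pass procedure: fences contract after
        # removal, so a second pass may remove more but never restores
        first = iqr_outlier_filter(values)
        if first.kept.size < 4:
            return
        second = iqr_outlier_filter(first.kept)
        kept_twice = set(second.kept.tolist())
        assert kept_twice <= set(first.kept.tolist())

    def test_per_tree_grouping(self):
        df = pd.DataFrame({
            "tree_tag": ["a"] * 5 + ["b"] * 5,
            "ea": [1.0, 2.0, 3.0, 4.0, 100.0, 100.0, 101.0, 102.0, 103.0, 104.0],
        })
        out = filter_flux_table(df)
        assert (out.loc[df.tree_tag == "a", "qc_flag"] == "outlier").sum() == 1
        # 100 is typical for tree b, an outlier only for tree a
        assert (out.loc[df.tree_tag == "b", "qc_flag"] == "ok").all()


class TestProcessClosures:
    def test_known_fluxes_recovered_and_flagged(self, chamber, rng):
        table = generate_chamber_closures(
            {"t1": 2.0, "t2": 4.0}, chamber, noise_sd=0.3, rng=rng)
        # append a pure-noise closure: no linear rise, poor r2 -> leak flag
        noise = table[table.closure_id == "c0000"].copy()
        noise["closure_id"] = "bad"
        noise["tree_tag"] = "t3"
        noise["co2_umol_mol"] = 420.0 + rng.normal(0, 2.0, len(noise))
        out = process_closures(pd.concat([table, noise]), chamber)
        out = out.set_index("tree_tag")
        assert out.loc["t1", "ea_raw"] == pytest.approx(2.0, abs=0.1)
        assert out.loc["t2", "ea_raw"] == pytest.approx(4.0, abs=0.1)
        assert out.loc["t3", "qc_flag"] == "leak"
        assert (out.loc[["t1", "t2"], "qc_flag"] == "ok").all()

    def test_q10_option_standardizes(self, chamber, rng):
        table = generate_chamber_closures({"t1": 2.0}, chamber, noise_sd=0.0,
                                          rng=rng)
        table["temp_c"] = 35.0
        raw = process_closures(table, chamber, q10=None)
        std = process_closures(table, chamber, q10=2.0, reference_t=25.0)
        assert std["ea"].iloc[0] == pytest.approx(raw["ea"].iloc[0] / 2.0, rel=1e-3)
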