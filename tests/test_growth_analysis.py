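import numpy as np
import pytest

from sightkit.errors import DegenerateFitError, DomainError, RangeError
from sightkit.growth_analysis import (
    Calibration,
    GrowthCurve,
    analyze_plate,
    fit_calibration,
    glucose_from_coelution,
    growth_metrics,
    gv_to_od,
    read_layout,
    read_timeseries,
    write_layout,
    write_timeseries,
)

SLOPE, INTERCEPT = 0.078, -2.412  # published GV -> OD line


def logistic_curve(r=0.5, K=3.6, od0=0.05, t_end=30.0, dt=0.2):
    """Noiseless logistic growth observed through the GV transform."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    A = (K - od0) / od0
    od = K / (1 + A * np.exp(-r * t))
    gv = (od - INTERCEPT) / SLOPE
    return t, od, gv


class TestCalibration:
    def test_noiseless_pairs_recovered_exactly(self):
        gv = np.linspace(35, 110, 12)
        pairs = list(zip(gv, SLOPE * gv + INTERCEPT))
        cal = fit_calibration(pairs)
        assert cal.slope == pytest.approx(SLOPE, rel=1e-12)
        assert cal.intercept == pytest.approx(INTERCEPT, rel=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_identity_line(self):
        pairs = [(0, 0), (1, 1), (2, 2), (5, 5)]
        cal = fit_calibration(pairs)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_pairs_recover_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        gv = rng.uniform(35, 110, size=50)
        od = SLOPE * gv + INTERCEPT + rng.normal(0, 0.1, size=50)
        cal = fit_calibration(list(zip(gv, od)))
        # closed-form OLS standard error of the slope on this sample
        resid = od - (cal.slope * gv + cal.intercept)
        se = np.sqrt(
            (resid @ resid / (len(gv) - 2)) / ((gv - gv.mean()) @ (gv - gv.mean()))
        )
        assert abs(cal.slope - SLOPE) < 3 * se

    def test_degenerate_gv_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([(50, 1.0), (50, 1.2), (50, 1.4)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DomainError):
            fit_calibration([(1, 1), (2, 2)])


class TestGvToOd:
    def test_valid_gv_min_maps_to_zero(self):
        cal = Calibration(SLOPE, INTERCEPT, 1.0)
        result = gv_to_od(cal.valid_gv_min, cal)
        assert result.od == pytest.approx(0.0, abs=1e-12)

    def test_identity_calibration(self):
        cal = Calibration(1.0, 0.0, 1.0)
        assert gv_to_od(5.0, cal).od == pytest.approx(5.0)

    def test_below_calibration_clamped_and_flagged(self):
        cal = Calibration(SLOPE, INTERCEPT, 1.0)
        result = gv_to_od(10.0, cal)  # far below valid_gv_min ~ 30.9
        assert result.od == 0.0
        assert result.below_calibration

    def test_vectorized_conversion(self):
        cal = Calibration(SLOPE, INTERCEPT, 1.0)
        od, below = gv_to_od(np.array([10.0, 100.0]), cal)
        assert below.tolist() == [True, False]
        assert od[1] == pytest.approx(SLOPE * 100 + INTERCEPT)


class TestGrowthMetrics:
    def test_flat_curve_is_unreliable_with_zero_delta(self):
        t = np.arange(0, 12.5, 0.5)
        curve = GrowthCurve("A1", t, np.full_like(t, 31.0))
        m = growth_metrics(curve)
        assert not m.reliable
        assert m.delta_green_value == 0.0
        assert m.lag_time is None and m.max_rate is None

    def test_logistic_rate_bracketed_by_analytic_oracle(self):
        r, K, od0 = 0.5, 3.6, 0.05
        dt, window = 0.2, 5
        t, od, gv = logistic_curve(r, K, od0, dt=dt)
        blank = -INTERCEPT / SLOPE
        m = growth_metrics(GrowthCurve("A1", t, gv), blank_gv=blank,
                           rate_window=window)
        # Oracle: the analytic log-slope of a logistic is r (1 - od/K),
        # monotonically decreasing, so the maximum windowed OLS slope is
        # attained in the first admissible window (signal >= 20% of the
        # dynamic range) and must lie between the analytic slopes at that
        # window's end and start.
        od_enter = od0 + 0.2 * (od.max() - od0)
        t_enter = t[np.argmax(od >= od_enter)]
        od_exit = np.interp(t_enter + (window - 1) * dt, t, od)
        upper = r * (1 - od_enter / K)
        lower = r * (1 - od_exit / K)
        assert lower * (1 - 1e-9) <= m.max_rate <= upper * (1 + 1e-9)

    def test_time_shift_moves_lag_by_the_shift(self):
        r, K, od0 = 0.5, 3.6, 0.05
        t, od, gv = logistic_curve(r, K, od0, t_end=40.0)
        shift = 4.0
        od_shifted = np.where(t < shift, od0,
                              np.interp(t - shift, t, od))
        gv_shifted = (od_shifted - INTERCEPT) / SLOPE
        m0 = growth_metrics(GrowthCurve("A1", t, gv), delta_times=(0, 10))
        m1 = growth_metrics(GrowthCurve("A2", t, gv_shifted), delta_times=(0, 10))
        assert m1.lag_time - m0.lag_time == pytest.approx(shift, abs=0.2)

    def test_lag_and_stationary_invariant_under_affine_gv_rescaling(self):
        t, od, gv = logistic_curve()
        m = growth_metrics(GrowthCurve("A1", t, gv))
        m_scaled = growth_metrics(GrowthCurve("A1", t, 3.0 * gv + 17.0))
        assert m_scaled.lag_time == pytest.approx(m.lag_time, abs=1e-9)
        assert m_scaled.t_stationary == pytest.approx(m.t_stationary, abs=1e-9)

    def test_delta_green_value_interpolates_between_stated_times(self):
        t = np.array([0.0, 4.0, 8.0, 12.0])
        gv = np.array([30.0, 40.0, 60.0, 62.0])
        m = growth_metrics(GrowthCurve("A1", t, gv), delta_times=(0, 10))
        assert m.delta_green_value == pytest.approx(61.0 - 30.0)

    def test_delta_times_outside_span_raise(self):
        t = np.arange(0, 5.0, 0.5)
        curve = GrowthCurve("A1", t, np.linspace(30, 60, len(t)))
        with pytest.raises(RangeError):
            growth_metrics(curve, delta_times=(0, 10))


class TestCoelutionCorrection:
    @pytest.mark.parametrize(
        "mixed,gluconate,expected",
        [(15.0, 5.0, 10.0), (15.0, 0.0, 15.0), (7.0, 7.0, 0.0)],
    )
    def test_subtraction(self, mixed, gluconate, expected):
        assert glucose_from_coelution(mixed, gluconate) == pytest.approx(expected)

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert glucose_from_coelution(3.0, 5.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            glucose_from_coelution(-1.0, 0.0)


class TestCsvRoundTrips:
    def test_timeseries_round_trip(self, tmp_path):
        import pandas as pd

        t = np.arange(0, 3.0, 0.5)
        df = pd.DataFrame(
            {"A1": np.linspace(30, 60, len(t)), "A2": np.linspace(31, 59, len(t))},
            index=pd.Index(t, name="time_h"),
        )
        path = tmp_path / "gv.csv"
        write_timeseries(df, path)
        back = read_timeseries(path)
        assert np.allclose(back.to_numpy(), df.to_numpy())
        assert list(back.columns) == ["A1", "A2"]

    def test_layout_round_trip(self, tmp_path):
        import pandas as pd

        layout = pd.DataFrame(
            {"condition": ["blank", "styrene_1mM"], "dose_ul": [0.0, 0.14]},
            index=pd.Index(["A1", "A2"], name="well"),
        )
        path = tmp_path / "plate.csv"
        write_layout(layout, path)
        back = read_layout(path)
        assert list(back.index) == ["A1", "A2"]
        assert list(back["condition"]) == ["blank", "styrene_1mM"]

    def test_analyze_plate_uses_blank_wells_and_skips_them(self):
        import pandas as pd

        t, od, gv = logistic_curve()
        blank_level = -INTERCEPT / SLOPE
        df = pd.DataFrame(
            {"A1": gv, "A2": np.full_like(gv, blank_level)},
            index=pd.Index(t, name="time_h"),
        )
        layout = pd.DataFrame(
            {"condition": ["growth", "blank"]},
            index=pd.Index(["A1", "A2"], name="well"),
        )
        out = analyze_plate(df, layout, delta_times=(0, 10))
        assert list(out.index) == ["A1"]
        assert out.loc["A1", "reliable"]
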