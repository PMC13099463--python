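"""Chart fitting: accuracy, calibration, noncrossing, lookup, round trip."""

import json

import numpy as np
import pytest
from scipy.stats import norm

from funsi.charts import (
    DEFAULT_TAUS,
    CentileChart,
    ChartConfig,
    ChartFitError,
    ChartParseError,
    centile_position,
    fit_chart,
    fit_chart_set,
    load_chart_set,
    save_chart_set,
)
from funsi.features import FEATURE_NAMES


class TestFitChart:
    def test_constant_values_give_flat_curves(self):
        rng = np.random.default_rng(0)
        ser = rng.uniform(-12, 0, 1000)
        chart = fit_chart(ser, np.full(1000, 3.7))
        vals = chart.evaluate_grid(np.linspace(-12, 0, 101))
        assert np.max(np.abs(vals - 3.7)) < 1e-6

    def test_location_shift_recovers_closed_form_quantiles(
        self, location_shift_chart
    ):
        chart, _, _ = location_shift_chart
        gx = np.linspace(-12, 0, 25)
        vals = chart.evaluate_grid(gx)
        for j, tau in ((9, 0.50), (18, 0.95), (0, 0.05)):
            truth = 2.0 + 0.1 * gx + 0.5 * norm.ppf(tau)
            assert np.max(np.abs(vals[:, j] - truth)) < 0.05

    def test_training_coverage_calibrated(self, location_shift_chart):
        chart, ser, y = location_shift_chart
        vals = chart.evaluate_grid(ser)
        for j, tau in enumerate(chart.taus):
            frac_below = float(np.mean(y < vals[:, j]))
            assert abs(frac_below - tau) <= 0.01

    def test_noncrossing_on_dense_grid(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        vals = chart.evaluate_grid(np.linspace(-12, 0, 201))
        assert np.min(np.diff(vals, axis=1)) >= -1e-9

    def test_single_tau_matches_textbook_quantile_regression(self):
        """With one tau and no penalty the noncrossing machinery is
        inactive; the fit must reach the unconstrained optimum."""
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 2000
        ser = rng.uniform(-12, 0, n)
        y = 1.0 - 0.2 * ser + rng.normal(0, 0.4, n) * (1 + 0.05 * np.abs(ser))
        cfg = ChartConfig(penalty=0.0)
        chart = fit_chart(ser, y, taus=(0.25,), config=cfg)
        from scipy.interpolate import BSpline

        B = BSpline.design_matrix(ser, chart.knots, chart.degree).toarray()
        ref = statsmodels.QuantReg(y, B).fit(q=0.25, max_iter=5000)

        def mean_loss(coef):
            r = y - B @ coef
            return float(np.mean(r * (0.25 - (r < 0))))

        assert mean_loss(chart.coef[0]) <= mean_loss(np.asarray(ref.params)) + 1e-6

    def test_error_cases(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ChartFitError):
            fit_chart(np.linspace(-5, -1, 5), rng.normal(size=5))  # too few
        with pytest.raises(ChartFitError):
            fit_chart(np.full(300, -3.0), rng.normal(size=300))  # no variation


class TestChartSet:
    def test_ten_charts_with_nineteen_curves(self, fitted_chart_set):
        charts, _ = fitted_chart_set
        assert set(charts.charts) == set(FEATURE_NAMES)
        for chart in charts.charts.values():
            assert len(chart.taus) == 19
            assert chart.coef.shape[0] == 19

    def test_refit_is_deterministic(self, default_cohort, fitted_chart_set):
        charts, selected = fitted_chart_set
        again = fit_chart_set(selected.head(600))
        again2 = fit_chart_set(selected.head(600))
        for name in FEATURE_NAMES:
            np.testing.assert_array_equal(again[name].coef, again2[name].coef)

    def test_generator_trend_recovered_in_median_curve(self, fitted_chart_set):
        """Arterial tortuosity decreases with myopia, so its median
        curve must be lower at SER = -10 than at SER = 0."""
        charts, _ = fitted_chart_set
        chart = charts["arterial_tortuosity"]
        med_low = chart.evaluate(-10.0)[9]
        med_high = chart.evaluate(0.0)[9]
        assert med_low < med_high

    def test_missing_feature_column_is_schema_error(self, default_cohort):
        _, _, eyes = default_cohort
        broken = eyes.drop(columns=["avr"]).head(500)
        with pytest.raises(ValueError, match="avr"):
            fit_chart_set(broken)


class TestEvaluateAndLookup:
    def test_evaluate_sorted_and_clamped(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        vals = chart.evaluate(-5.0)
        assert np.all(np.diff(vals) >= 0)
        with pytest.warns(UserWarning, match="clamped"):
            outside = chart.evaluate(-15.0)
        np.testing.assert_array_equal(outside, chart.evaluate(-12.0))

    def test_value_on_median_curve_maps_to_half(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        median = chart.evaluate(-2.0)[9]
        assert centile_position(chart, -2.0, median) == 0.5

    def test_extreme_values_capped(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        assert centile_position(chart, -2.0, 1e9) == 0.95
        assert centile_position(chart, -2.0, -1e9) == 0.05

    def test_tie_breaks_to_lower_tau(self):
        # hand-built chart with two exactly coincident adjacent curves:
        # the tie at their shared value must resolve to the lower tau
        cfg = ChartConfig()
        p = cfg.n_basis
        chart = CentileChart(
            feature_name="toy",
            taus=np.array([0.45, 0.50, 0.55]),
            knots=cfg.knots(),
            degree=cfg.degree,
            coef=np.vstack([np.full(p, 1.0), np.full(p, 1.0), np.full(p, 3.0)]),
            ser_domain=cfg.domain,
        )
        shared = chart.evaluate(-3.0)[0]
        assert centile_position(chart, -3.0, shared) == 0.45
        assert centile_position(chart, -3.0, 2.9) == 0.55

    def test_lookup_monotone_in_value(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        values = np.linspace(-1, 5, 200)
        cents = [centile_position(chart, -4.0, v) for v in values]
        assert np.all(np.diff(cents) >= 0)

    def test_non_finite_value_rejected(self, location_shift_chart):
        chart, _, _ = location_shift_chart
        with pytest.raises(ValueError):
            centile_position(chart, -2.0, np.nan)


class TestSerialization:
    def test_round_trip_is_bit_identical(self, fitted_chart_set, tmp_path):
        charts, _ = fitted_chart_set
        path = tmp_path / "charts.json"
        save_chart_set(charts, path)
        loaded = load_chart_set(path)
        grid = np.linspace(-12, 0, 101)
        for name in FEATURE_NAMES:
            np.testing.assert_array_equal(
                charts[name].evaluate_grid(grid), loaded[name].evaluate_grid(grid)
            )

    def test_missing_chart_is_parse_error(self, fitted_chart_set, tmp_path):
        charts, _ = fitted_chart_set
        path = tmp_path / "charts.json"
        save_chart_set(charts, path)
        payload = json.loads(path.read_text())
        del payload["charts"]["avr"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ChartParseError, match="missing feature"):
            load_chart_set(path)

    def test_crossing_curves_rejected_on_load(self, fitted_chart_set, tmp_path):
        charts, _ = fitted_chart_set
        path = tmp_path / "charts.json"
        save_chart_set(charts, path)
        payload = json.loads(path.read_text())
        chart = payload["charts"]["avr"]
        chart["coef"][0], chart["coef"][18] = chart["coef"][18], chart["coef"][0]
        path.write_text(json.dumps(payload))
        with pytest.raises(ChartParseError, match="cross"):
            load_chart_set(path)
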