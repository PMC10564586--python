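import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greytrend import (EquidistantSeries, accumulate, adjacent_means,
                       applicability_class, estimate_parameters, fit_and_forecast,
                       restored_value, round_half_away)

from .conftest import MODELING_VECTOR


class TestAccumulation:
    def test_running_sums_of_modeling_vector(self):
        assert accumulate(MODELING_VECTOR) == pytest.approx(
            [10, 109.1, 209.3, 310.6, 412.9, 514.8], abs=1e-9)

    def test_single_element(self):
        assert accumulate([5.0]) == pytest.approx([5.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20))
    def test_first_difference_inverts_accumulation(self, values):
        ago = accumulate(values)
        recovered = np.diff(np.concatenate([[0.0], ago]))
        assert recovered == pytest.approx(values, rel=1e-12, abs=1e-9)


class TestAdjacentMeans:
    def test_means_of_modeling_vector(self):
        z = adjacent_means(accumulate(MODELING_VECTOR))
        assert z == pytest.approx([59.55, 159.20, 259.95, 361.75, 463.85], abs=1e-9)

    @pytest.mark.parametrize("ago, expected", [([2, 4], [3]), ([1, 2, 3], [1.5, 2.5])])
    def test_small_cases(self, ago, expected):
        assert adjacent_means(ago) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            adjacent_means([1.0])


class TestEstimation:
    def test_worked_example_parameters(self, fitted_model):
        # frozen unrounded oracle from an independent normal-equation solve
        assert fitted_model.a == pytest.approx(-0.0076032, abs=5e-7)
        assert fitted_model.b == pytest.approx(98.9766227, abs=5e-6)
        assert fitted_model.n_fit == 5

    def test_matches_generic_least_squares_on_random_series(self):
        """Closed centered-form solve agrees with numpy's lstsq on the
        regression matrix B = [-z | 1] to 1e-9 relative."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 12)
            values = tuple(rng.uniform(0.5, 100.0, size=n))
            series = EquidistantSeries(origin_year=2000, step_years=5, values=values)
            model = estimate_parameters(series)
            z = adjacent_means(accumulate(values))
            B = np.column_stack([-z, np.ones_like(z)])
            (a_ls, b_ls), *_ = np.linalg.lstsq(B, np.asarray(values[1:]), rcond=None)
            assert model.a == pytest.approx(a_ls, rel=1e-9, abs=1e-12)
            assert model.b == pytest.approx(b_ls, rel=1e-9)

    def test_constant_series_gives_degenerate_model(self):
        series = EquidistantSeries(origin_year=2000, step_years=5,
                                   values=(10.0, 7.0, 7.0, 7.0, 7.0), has_prefix=True)
        model = estimate_parameters(series)
        assert model.a == pytest.approx(0.0, abs=1e-12)
        assert model.b == pytest.approx(7.0)
        assert model.restored_coefficient == pytest.approx(7.0)
        assert restored_value(model, 9) == pytest.approx(7.0)

    def test_too_short_series_rejected(self):
        series = EquidistantSeries(origin_year=2000, step_years=5, values=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="fewer than 4 data"):
            estimate_parameters(series)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(log_rho=st.floats(-0.3, 0.3), c=st.floats(0.1, 1e3), n=st.integers(5, 10))
    def test_exact_geometric_input_recovers_pade_coefficient(self, log_rho, c, n):
        """On noise-free x(k) = c rho^(k-1) the regression has zero residuals
        and a-hat = -2(rho-1)/(rho+1), within |ln rho|^3 of -ln rho."""
        rho = math.exp(log_rho)
        values = tuple(c * rho ** k for k in range(n))
        series = EquidistantSeries(origin_year=2000, step_years=1, values=values)
        model = estimate_parameters(series)
        assert model.a == pytest.approx(-2 * (rho - 1) / (rho + 1), rel=1e-7, abs=1e-12)
        assert abs(model.a + log_rho) <= abs(log_rho) ** 3 + 1e-12
        # zero regression residuals: the affine relation x + a z = b is exact
        z = adjacent_means(accumulate(values))
        resid = np.asarray(values[1:]) + model.a * z - model.b
        assert np.max(np.abs(resid)) <= 1e-9 * c
        # restored values reproduce the input up to the trapezoid-form bias,
        # which is second order in the per-step log ratio
        _, fitted = fit_and_forecast(model, 0)
        assert fitted == pytest.approx(values[1:], rel=log_rho ** 2 + 1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(delta=st.floats(-5.0, 200.0))
    def test_prefix_shift_moves_b_by_a_delta(self, delta):
        base = EquidistantSeries(origin_year=2000, step_years=5,
                                 values=MODELING_VECTOR, has_prefix=True)
        shifted = EquidistantSeries(origin_year=2000, step_years=5,
                                    values=(10.0 + delta,) + MODELING_VECTOR[1:],
                                    has_prefix=True)
        if 10.0 + delta <= 0:
            return
        m0, m1 = estimate_parameters(base), estimate_parameters(shifted)
        assert m1.a == pytest.approx(m0.a, rel=1e-10)
        assert m1.b - m0.b == pytest.approx(m0.a * delta, rel=1e-7, abs=1e-9)


class TestRestoredFunction:
    def test_worked_example_coefficient(self, fitted_model):
        assert fitted_model.restored_coefficient == pytest.approx(98.6772, abs=1e-3)

    def test_fitted_2020_value(self, fitted_model):
        assert round_half_away(restored_value(fitted_model, 6)) == 102.5

    def test_slot_one_never_restored(self, fitted_model):
        with pytest.raises(ValueError):
            restored_value(fitted_model, 1)

    def test_equals_ago_difference(self, fitted_model):
        """Restored values equal consecutive differences of the accumulated
        trajectory xhat(1)(m) = (x1 - b/a) e^(-a(m-1)) + b/a."""
        a, b, x1 = fitted_model.a, fitted_model.b, fitted_model.x1

        def x1_hat(m):
            return (x1 - b / a) * math.exp(-a * (m - 1)) + b / a

        for m in range(2, 12):
            assert restored_value(fitted_model, m) == pytest.approx(
                x1_hat(m) - x1_hat(m - 1), rel=1e-9)


class TestForecasting:
    def test_worked_example_fit_and_horizon(self, fitted_model):
        years, values = fit_and_forecast(fitted_model, horizon_steps=2)
        assert years == (2000, 2005, 2010, 2015, 2020, 2025, 2030)
        rounded = [round_half_away(v) for v in values]
        assert rounded[:5] == [99.4, 100.2, 101.0, 101.7, 102.5]
        assert rounded[5] == 103.3
        # pure exponential extrapolation for 2030 (the published table damps it)
        assert rounded[6] == 104.1

    def test_zero_horizon_returns_fitted_only(self, fitted_model):
        years, values = fit_and_forecast(fitted_model, horizon_steps=0)
        assert years == (2000, 2005, 2010, 2015, 2020)
        assert len(values) == 5

    def test_consecutive_ratio_is_constant(self, fitted_model):
        _, values = fit_and_forecast(fitted_model, horizon_steps=4)
        ratios = values[1:] / values[:-1]
        assert ratios == pytest.approx(math.exp(-fitted_model.a), rel=1e-12)

    def test_negative_a_gives_strictly_increasing_fit(self, fitted_model):
        assert fitted_model.a < 0
        _, values = fit_and_forecast(fitted_model, horizon_steps=2)
        assert np.all(np.diff(values) > 0)


class TestApplicability:
    @pytest.mark.parametrize("a, expected", [
        (-0.0076, "short_medium_term_ok"),
        (-0.3, "short_medium_term_ok"),   # boundary is inclusive
        (-0.5, "out_of_range"),
    ])
    def test_development_coefficient_range(self, fitted_model, a, expected):
        model = fitted_model.__class__(**{**fitted_model.__dict__, "a": a})
        assert applicability_class(model) == expected


class TestSerialization:
    def test_round_trip_fields(self, fitted_model):
        import json
        payload = json.loads(fitted_model.to_json())
        assert payload["a"] == fitted_model.a
        assert payload["origin_year"] == 2000
        assert payload["has_prefix"] is True
        assert payload["n_fit"] == 5
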