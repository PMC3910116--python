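"""Standard-curve fitting, inversion and relative-activity quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spychap import chaperone_activity as ca
from spychap import synthetic_data as sd
from spychap.errors import FitRejectedError, InvalidInputError, OutOfRangeError


def _const_trace(value, assay="alpha_la", ratio=0.1):
    t = np.arange(0.0, 601.0)
    return ca.AggregationTrace(t, np.full_like(t, value), assay, ratio)


class TestEndpoints:
    def test_constant_trace_returns_value_everywhere(self):
        ep = ca.extract_endpoints(_const_trace(0.05), [300, 400, 500, 600])
        assert np.allclose(ep, 0.05)

    def test_synthetic_endpoint_equals_generator_truth(self):
        syn = sd.gen_aggregation_trace("alpha_la", 0.2)
        ep = ca.extract_endpoints(syn.data, [400.0])
        assert ep[0] == pytest.approx(syn.truth["endpoint"], rel=1e-12)

    def test_out_of_range_time_raises(self):
        with pytest.raises(OutOfRangeError):
            ca.extract_endpoints(_const_trace(0.05), [700.0])


class TestAggregationSlope:
    def test_linear_trace_slope_exact(self):
        t = np.arange(0.0, 601.0)
        tr = ca.AggregationTrace(t, 3.5 * t + 2.0, "aldolase", 0.3)
        assert ca.fit_aggregation_slope(tr) == pytest.approx(3.5, rel=1e-12)

    def test_window_excludes_early_curvature(self):
        """Curvature confined to t < 50 s does not affect the 50-600 s slope."""
        t = np.arange(0.0, 601.0)
        y = 2.0 * t
        y[t < 50] = (t[t < 50] / 50.0) ** 3 * 100.0
        tr = ca.AggregationTrace(t, y, "aldolase", 0.3)
        assert ca.fit_aggregation_slope(tr) == pytest.approx(2.0, rel=1e-12)

    def test_synthetic_aldolase_slope_matches_calibration(self):
        syn = sd.gen_aggregation_trace("aldolase", 0.3)
        slope = ca.fit_aggregation_slope(syn.data)
        assert slope == pytest.approx(21.0535, abs=1e-3)

    def test_insufficient_coverage_raises(self):
        t = np.arange(0.0, 301.0)
        tr = ca.AggregationTrace(t, 2.0 * t, "aldolase", 0.3)
        with pytest.raises(InvalidInputError):
            ca.fit_aggregation_slope(tr)


class TestStandardCurveFit:
    def test_exponential_round_trip(self):
        x = np.linspace(0, 2, 22)
        y = 0.004 + 0.108 * np.exp(-8.46 * x)
        curve = ca.fit_standard_curve(list(zip(x, y)), "exponential")
        assert curve.coefficients == pytest.approx((0.004, 0.108, 8.46), rel=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_round_trip(self):
        x = np.linspace(0, 1, 6)
        y = 29.0861 * x**2 - 65.0189 * x + 37.9414
        curve = ca.fit_standard_curve(list(zip(x, y)), "quadratic")
        assert curve.coefficients == pytest.approx(
            (29.0861, -65.0189, 37.9414), rel=1e-9
        )

    def test_power_round_trip_r_squared(self):
        x = np.linspace(0, 1.75, 9)
        y = 1.27711 * (x + 0.02196) ** 0.18859
        curve = ca.fit_standard_curve(list(zip(x, y)), "power")
        assert curve.coefficients == pytest.approx(
            (1.27711, 0.02196, 0.18859), rel=1e-5
        )
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_non_monotone_fit_rejected(self):
        """A quadratic whose vertex lies inside the data span is not invertible."""
        x = np.linspace(0, 2, 9)
        y = (x - 1.0) ** 2
        with pytest.raises(FitRejectedError):
            ca.fit_standard_curve(list(zip(x, y)), "quadratic")

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            ca.fit_standard_curve([(0, 1), (1, 0.5), (2, 0.2)], "exponential")


class TestInversion:
    def test_alpha_la_worked_example(self):
        """Readout 0.009 on the 400 s calibration back-interpolates to an
        effective ratio of 0.363, i.e. 1.82-fold at added ratio 0.2."""
        eff = ca.invert_standard_curve(ca.ALPHA_LA_400S_CURVE, 0.009)
        assert eff == pytest.approx(np.log(0.108 / 0.005) / 8.46, rel=1e-12)
        assert round(eff, 3) == 0.363
        assert round(eff / 0.2, 2) == 1.82

    def test_zero_ratio_readout_inverts_to_zero(self):
        a, b, _ = ca.ALPHA_LA_400S_CURVE.coefficients
        assert ca.invert_standard_curve(ca.ALPHA_LA_400S_CURVE, a + b) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_quadratic_round_trip_smaller_root(self):
        y = float(ca.ALDOLASE_AGG_CURVE(0.3))
        x = ca.invert_standard_curve(ca.ALDOLASE_AGG_CURVE, y)
        assert x == pytest.approx(0.3, rel=1e-12)

    def test_quadratic_root_choice_matches_brute_force(self):
        """The returned root is the one at or left of the vertex, verified
        against exhaustive root enumeration."""
        a2, a1, a0 = ca.ALDOLASE_AGG_CURVE.coefficients
        vertex = -a1 / (2 * a2)
        for y in [5.0, 10.0, 21.05, 30.0]:
            roots = np.roots([a2, a1, a0 - y])
            valid = sorted(r.real for r in roots if abs(r.imag) < 1e-12)
            got = ca.invert_standard_curve(ca.ALDOLASE_AGG_CURVE, y)
            assert got == pytest.approx(valid[0], rel=1e-9)
            assert got <= vertex + 1e-12

    def test_inversion_agrees_with_dense_grid_search(self):
        """Analytic inversion matches a brute-force grid scan of each family."""
        cases = [
            (ca.ALPHA_LA_400S_CURVE, 0.009, (0.0, 2.0)),
            (ca.ALDOLASE_AGG_CURVE, 21.0535, (0.0, 1.0)),
            (ca.ALDOLASE_REFOLD_CURVE, 1.119, (0.0, 1.75)),
        ]
        for curve, y, (lo, hi) in cases:
            grid = np.linspace(lo, hi, 200001)
            best = grid[np.argmin(np.abs(curve(grid) - y))]
            got = ca.invert_standard_curve(curve, y)
            assert abs(got - best) <= (hi - lo) / 200000

    def test_out_of_range_readouts_raise_named_bounds(self):
        with pytest.raises(OutOfRangeError, match="floor"):
            ca.invert_standard_curve(ca.ALPHA_LA_400S_CURVE, 0.004)
        with pytest.raises(OutOfRangeError, match="maximum"):
            ca.invert_standard_curve(ca.ALPHA_LA_400S_CURVE, 0.5)
        with pytest.raises(OutOfRangeError):
            ca.invert_standard_curve(ca.ALDOLASE_AGG_CURVE, 0.5)  # below minimum


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    a=st.floats(0.0, 0.1),
    b=st.floats(0.01, 1.0),
    k=st.floats(0.5, 10.0),
    x=st.floats(0.0, 1.0),
)
def test_exponential_invert_evaluate_identity(a, b, k, x):
    # k*x <= 10 keeps y - A away from the floor, where inversion is defined
    curve = ca.StandardCurve("exponential", (a, b, k))
    y = float(curve(x))
    assert ca.invert_standard_curve(curve, y) == pytest.approx(x, rel=1e-6, abs=1e-6)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    a2=st.floats(1.0, 50.0),
    a1=st.floats(-100.0, -10.0),
    a0=st.floats(10.0, 100.0),
    frac=st.floats(0.0, 0.99),
)
def test_quadratic_invert_evaluate_identity_on_decreasing_branch(a2, a1, a0, frac):
    vertex = -a1 / (2 * a2)
    x = frac * vertex
    curve = ca.StandardCurve("quadratic", (a2, a1, a0))
    y = float(curve(x))
    assert ca.invert_standard_curve(curve, y) == pytest.approx(x, abs=1e-6)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    c=st.floats(0.1, 5.0),
    x0=st.floats(1e-3, 0.5),
    p=st.floats(0.05, 1.0),
    x=st.floats(0.0, 2.0),
)
def test_power_invert_evaluate_identity(c, x0, p, x):
    # small exponents amplify relative error ~1/p on inversion
    curve = ca.StandardCurve("power", (c, x0, p))
    y = float(curve(x))
    assert ca.invert_standard_curve(curve, y) == pytest.approx(x, rel=1e-6, abs=1e-6)


def test_monotonicity_higher_endpoint_means_lower_effective_ratio():
    ys = np.linspace(0.01, 0.1, 20)
    effs = [ca.invert_standard_curve(ca.ALPHA_LA_400S_CURVE, y) for y in ys]
    assert np.all(np.diff(effs) < 0)


class TestRelativeActivity:
    def test_zero_noise_fold_is_exact(self):
        """At zero noise the quantification returns the generator's fold."""
        fold_true = 2.12
        obs = []
        curves = [
            ca.StandardCurve("exponential", ca.ALPHA_LA_400S_CURVE.coefficients,
                             endpoint_s=s)
            for s in (300.0, 400.0, 500.0, 600.0)
        ]
        for added in (0.1, 0.15, 0.2):
            syn = sd.gen_aggregation_trace("alpha_la", fold_true * added)
            for s, y in zip(
                (300.0, 400.0, 500.0, 600.0),
                ca.extract_endpoints(syn.data, (300, 400, 500, 600)),
            ):
                obs.append(ca.ActivityObservation(added, float(y), endpoint_s=s))
        res = ca.relative_activity(obs, curves, assay="alpha_la")
        assert res.fold_vs_wt == pytest.approx(fold_true, rel=1e-9)
        assert res.n_values_averaged == 12

    def test_wild_type_self_test_near_unity_at_assay_noise(self):
        """The wild-type control re-quantified against its own calibration
        averages to ~1 at realistic assay noise (the 1.06 +/- 0.09 check)."""
        rng = np.random.default_rng(11)
        obs = []
        for rep in range(2):
            for added in (0.1, 0.15, 0.2):
                y_true = float(ca.ALPHA_LA_400S_CURVE(added))
                for s in (300.0, 400.0, 500.0, 600.0):
                    y = y_true + rng.normal(0.0, 0.001)
                    obs.append(ca.ActivityObservation(added, y, endpoint_s=s))
        curves = [
            ca.StandardCurve("exponential", ca.ALPHA_LA_400S_CURVE.coefficients,
                             endpoint_s=s)
            for s in (300.0, 400.0, 500.0, 600.0)
        ]
        res = ca.relative_activity(obs, curves)
        assert res.n_values_averaged == 24
        assert abs(res.fold_vs_wt - 1.0) <= 0.09

    def test_out_of_range_observation_is_identified(self):
        with pytest.raises(OutOfRangeError, match="readout=0.001"):
            ca.relative_activity(
                [ca.ActivityObservation(0.2, 0.001, endpoint_s=400.0)],
                [ca.ALPHA_LA_400S_CURVE],
            )


class TestRefoldingYield:
    def test_native_slope_ratio(self):
        t = np.linspace(0, 300, 31)
        native_slope = -2e-3
        trace = list(zip(t, 1.0 + native_slope * t))
        assert ca.refolding_yield(trace, native_slope) == pytest.approx(1.0)
        flat = list(zip(t, np.ones_like(t)))
        assert ca.refolding_yield(flat, native_slope) == pytest.approx(0.0, abs=1e-12)

    def test_fractional_yield_by_construction(self):
        t = np.linspace(0, 300, 31)
        native_slope = -2e-3
        trace = list(zip(t, 1.0 + 0.474 * native_slope * t))
        assert ca.refolding_yield(trace, native_slope) == pytest.approx(0.474)

    def test_zero_native_slope_raises(self):
        t = np.linspace(0, 300, 31)
        with pytest.raises(InvalidInputError):
            ca.refolding_yield(list(zip(t, t)), 0.0)
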