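"""Curve sampling, gradients, OLS regression and the PQ-reference comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from avtpace import (
    ApVsCurve,
    Method,
    PqReference,
    build_curve,
    compare_to_reference,
    curve_gradient,
    default_pq_reference,
    fit_regression,
    observer_regressions,
    pq_reference_curve,
)


def test_build_curve_m10_grid_and_minimum(m10_curve):
    assert m10_curve.n == 10
    assert m10_curve.ap_vs.min() == pytest.approx(60000 / 220 - 190)
    assert m10_curve.hr[m10_curve.ap_vs.argmin()] == 220


def test_build_curve_m20_grid_and_minimum(m20_curve):
    assert m20_curve.n == 9
    assert m20_curve.ap_vs.min() == pytest.approx(60000 / 210 - 190)


def test_build_curve_single_sample():
    c = build_curve("M10", 130, 130, 10)
    assert c.n == 1
    assert c.ap_vs[0] == pytest.approx(60000 / 130 - 350)


def test_build_curve_names_offending_rate():
    with pytest.raises(ValueError, match="220"):
        build_curve("M20", 130, 220, 10)


def test_gradient_of_constant_curve_is_zero():
    c = ApVsCurve(Method.MANUAL, np.array([100.0, 110, 120]), np.full(3, 150.0), (100, 120, 10))
    assert np.allclose(curve_gradient(c, "exact")[:, 1], 0.0)


def test_m10_curve_is_not_monotone(m10_curve):
    g = curve_gradient(m10_curve, resolution="exact")
    by_hr = dict(zip(g[:, 0], g[:, 1]))
    assert by_hr[170.0] > 0  # 93.33 ms at 180 vs 92.94 ms at 170
    assert (g[:, 1] > 0).any() and (g[:, 1] < 0).any()


def test_m20_curve_monotone_at_device_resolution(m20_curve):
    # at integer-ms resolution the M20 curve never rises ...
    g = curve_gradient(m20_curve, resolution="device")
    assert (g[:, 1] <= 0).all()
    # ... though exact arithmetic has a sub-ms ripple between 170 and 180 bpm
    ge = curve_gradient(m20_curve, resolution="exact")
    assert dict(zip(ge[:, 0], ge[:, 1]))[170.0] == pytest.approx(0.0392, abs=1e-3)


def test_gradient_needs_two_samples():
    c = build_curve("M10", 150, 150, 10)
    with pytest.raises(ValueError):
        curve_gradient(c)


def test_regression_recovers_perfect_line():
    hr = np.arange(130.0, 221, 10)
    c = ApVsCurve(Method.MANUAL, hr, -0.5 * hr + 200, (130, 220, 10))
    r = fit_regression(c)
    assert r.slope == pytest.approx(-0.5, abs=1e-12)
    assert r.intercept == pytest.approx(200, abs=1e-9)
    assert r.r_squared == pytest.approx(1.0, abs=1e-12)


def test_regression_two_point_line():
    c = ApVsCurve(
        Method.MANUAL, np.array([130.0, 220.0]), np.array([111.5, 82.7]), (130, 220, 90)
    )
    assert fit_regression(c).slope == pytest.approx((82.7 - 111.5) / 90)


def test_m10_regression_matches_printed_gradient(m10_curve):
    r = fit_regression(m10_curve)
    assert round(r.slope, 2) == -0.28
    assert r.n == 10 and r.hr_range == (130.0, 220.0)


def test_regression_agrees_with_brute_force_oracle():
    # independent oracle: numerically minimise the SSE over (slope, intercept)
    rng = np.random.default_rng(42)
    for _ in range(5):
        hr = np.sort(rng.uniform(100, 220, size=8))
        hr += np.arange(8) * 1e-3  # ensure strictly increasing
        y = rng.uniform(80, 170, size=8)
        c = ApVsCurve(Method.MANUAL, hr, y, (hr[0], hr[-1], 0))
        r = fit_regression(c)

        def sse(p):
            return np.sum((y - (p[0] * hr + p[1])) ** 2)

        opt = minimize(sse, x0=[0.0, float(y.mean())], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert r.slope == pytest.approx(opt.x[0], abs=1e-5)
        assert r.intercept == pytest.approx(opt.x[1], abs=1e-3)


@given(shift=st.floats(-50, 50))
def test_adding_constant_shifts_intercept_only(shift, m10_curve):
    base = fit_regression(m10_curve)
    shifted = ApVsCurve(
        m10_curve.method, m10_curve.hr, m10_curve.ap_vs + shift, m10_curve.grid
    )
    r = fit_regression(shifted)
    assert r.slope == pytest.approx(base.slope, abs=1e-9)
    assert r.intercept == pytest.approx(base.intercept + shift, abs=1e-6)
    assert r.r_squared == pytest.approx(base.r_squared, abs=1e-9)


def test_regression_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_regression(build_curve("M10", 150, 150, 10))


def test_m20_closer_to_linearity_than_m10(m10_curve, m20_curve):
    assert fit_regression(m20_curve).r_squared > fit_regression(m10_curve).r_squared


def test_pq_reference_interpolation_and_offset():
    ref = PqReference(((100.0, 140.0), (200.0, 100.0)))
    out = pq_reference_curve(ref, [100, 150, 200])
    assert np.allclose(out[:, 1], [140, 120, 100])
    out10 = pq_reference_curve(ref.with_offset(10), [100, 150, 200])
    assert np.allclose(out10[:, 1] - out[:, 1], 10)


def test_pq_reference_rejects_query_outside_span():
    ref = default_pq_reference()
    with pytest.raises(ValueError):
        pq_reference_curve(ref, [40])


def test_default_pq_reference_is_monotone_standin():
    ref = default_pq_reference()
    vals = pq_reference_curve(ref, np.arange(60, 261))[:, 1]
    assert (np.diff(vals) <= 0).all()
    assert pq_reference_curve(ref, [100])[0, 1] == pytest.approx(160, abs=5)
    assert pq_reference_curve(ref, [220])[0, 1] == pytest.approx(100, abs=5)


def test_compare_to_reference_identity_and_offset():
    # a curve equal to the reference has zero residual everywhere
    hr = np.arange(100.0, 201, 10)
    vals = 180.0 - 0.4 * hr
    curve = ApVsCurve(Method.MANUAL, hr, vals, (100, 200, 10))
    ref = PqReference(tuple(zip(hr, vals)))
    cmp0 = compare_to_reference(curve, ref)
    assert np.allclose(cmp0.table["residual_ms"], 0)
    assert cmp0.mean_abs_residual == pytest.approx(0)
    cmp10 = compare_to_reference(curve, ref.with_offset(-10))
    assert np.allclose(cmp10.table["residual_ms"], 10)
    assert cmp10.mean_abs_residual == pytest.approx(10)


def test_compare_to_reference_standin_gives_finite_residuals(m20_curve):
    cmp = compare_to_reference(m20_curve, default_pq_reference(offset=10))
    assert len(cmp.table) == m20_curve.n
    assert np.isfinite(cmp.table["residual_ms"]).all()


def test_observer_fixture_shape_and_known_entries():
    df = observer_regressions()
    assert len(df) == 14  # calculated + six observers, two methods each
    calc = df[df["observer"] == "calculated"].set_index("method")
    assert calc.loc["M10", "gradient_ms_per_bpm"] == -0.28
    assert calc.loc["M20", "intercept_ms"] == 209
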