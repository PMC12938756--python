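"""Diffusion forward model: closed form, convolution and moments."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from neotrs import (
    InstrumentResponse,
    OpticalProperties,
    ProbeGeometry,
    TimeAxis,
    TPSFCurve,
    convolve_with_irf,
    diffusion_reflectance,
    mean_path_length_cw,
    mean_time,
    stationary_reflectance,
    total_reflectance,
)
from neotrs.forward import reflectance_density


def _symbolic_reflectance(mu_a, mu_sp, rho, n, t_ps, digits=30):
    """Independent arbitrary-precision evaluation of the closed form."""
    mu_a, mu_sp, rho = sp.Rational(mu_a), sp.Rational(mu_sp), sp.Rational(rho)
    n, t = sp.Rational(n), sp.Rational(t_ps)
    v = sp.Float("0.299792458", digits) / n
    D = 1 / (3 * mu_sp)
    z0 = 1 / mu_sp
    R = ((4 * sp.pi * D * v) ** sp.Rational(-3, 2) * z0
         * t ** sp.Rational(-5, 2)
         * sp.exp(-(rho ** 2 + z0 ** 2) / (4 * D * v * t))
         * sp.exp(-mu_a * v * t))
    return float(sp.N(R, digits))


@pytest.mark.parametrize("mu_a,mu_sp,t_ps", [
    ("0.01", "1.0", 1000),
    ("0.005", "0.7", 500),
    ("0.02", "1.2", 2000),
    ("0.015", "0.5", 800),
    ("0.001", "1.5", 3000),
])
def test_reflectance_matches_arbitrary_precision(mu_a, mu_sp, t_ps, geometry):
    """Closed form agrees with a symbolic evaluation to 10 significant digits."""
    exact = _symbolic_reflectance(mu_a, mu_sp, 30, "1.4", t_ps)
    ours = reflectance_density(float(t_ps),
                               OpticalProperties(801, float(sp.Rational(mu_a)),
                                                 float(sp.Rational(mu_sp))),
                               geometry)
    assert ours == pytest.approx(exact, rel=1e-10)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(mu_a=st.floats(1e-4, 0.1), mu_sp=st.floats(0.2, 3.0),
       rho=st.floats(10.0, 40.0))
def test_absorption_scaling_identity(mu_a, mu_sp, rho):
    """R(mu_a, t) = R(0, t) * exp(-mu_a v t) bin-wise (D independent of mu_a)."""
    axis = TimeAxis.regular(200, 25.0)
    geom = ProbeGeometry(rho)
    with_abs = diffusion_reflectance(
        OpticalProperties(801, mu_a, mu_sp), geom, axis).values
    no_abs = diffusion_reflectance(
        OpticalProperties(801, 0.0, mu_sp), geom, axis).values
    beer = no_abs * np.exp(-mu_a * geom.speed * axis.centers)
    np.testing.assert_allclose(with_abs, beer, rtol=1e-12)


def test_causality_and_finiteness(geometry):
    """Zero for t <= 0; overflow near t -> 0+ clamps to 0, never NaN."""
    axis = TimeAxis(np.arange(-5, 6) * 100.0)  # spans negative times
    curve = diffusion_reflectance(
        OpticalProperties(801, 0.01, 1.0), geometry, axis)
    centers = axis.centers
    assert np.all(curve.values[centers <= 0] == 0)
    assert np.all(np.isfinite(curve.values))
    # extremely early bins underflow the exponential -> exactly 0
    tiny = reflectance_density(1e-6, OpticalProperties(801, 0.01, 1.0),
                               geometry)
    assert tiny == 0.0


def test_invalid_optics_rejected():
    with pytest.raises(ValueError):
        OpticalProperties(801, -0.01, 1.0)
    with pytest.raises(ValueError):
        OpticalProperties(801, 0.01, 0.0)


class TestConvolution:
    def test_delta_identity(self, axis):
        rng = np.random.default_rng(0)
        tpsf = TPSFCurve(axis, rng.random(axis.n_bins))
        delta = np.zeros(axis.n_bins)
        delta[0] = 1.0
        out = convolve_with_irf(tpsf, TPSFCurve(axis, delta))
        np.testing.assert_allclose(out.values, tpsf.values, rtol=1e-12,
                                   atol=1e-15)

    def test_hand_example(self):
        axis = TimeAxis.regular(4, 1.0)
        out = convolve_with_irf(TPSFCurve(axis, [1, 2, 1, 0]),
                                TPSFCurve(axis, [0.5, 0.5, 0, 0]))
        np.testing.assert_allclose(out.values, [0.5, 1.5, 1.5, 0.5],
                                   atol=1e-12)

    def test_area_and_centroid_contracts(self):
        """Area multiplies; centroids add minus the first bin center,
        for 100 seeded random curve pairs (padded so no tail truncates)."""
        rng = np.random.default_rng(42)
        axis = TimeAxis.regular(256, 5.0)
        t0 = axis.centers[0]
        for _ in range(100):
            a = np.zeros(256)
            b = np.zeros(256)
            a[:100] = rng.random(100)
            b[:100] = rng.random(100)
            ca, cb = TPSFCurve(axis, a), TPSFCurve(axis, b)
            out = convolve_with_irf(ca, cb)
            assert out.area == pytest.approx(ca.area * cb.area, rel=1e-10)
            assert mean_time(out) == pytest.approx(
                mean_time(ca) + mean_time(cb) - t0, rel=1e-9)

    def test_axis_mismatch_names_both_widths(self, axis):
        other = TimeAxis.regular(1000, 20.0)
        tpsf = TPSFCurve(axis, np.ones(axis.n_bins))
        irf = TPSFCurve(other, np.ones(other.n_bins))
        with pytest.raises(ValueError, match="10.0.*20.0"):
            convolve_with_irf(tpsf, irf)


class TestTotalReflectance:
    def test_strictly_decreasing_in_mu_a(self, geometry):
        r1 = total_reflectance(OpticalProperties(801, 0.01, 1.0), geometry)
        r2 = total_reflectance(OpticalProperties(801, 0.02, 1.0), geometry)
        assert r2 < r1

    def test_continuous_at_zero_absorption(self, geometry):
        r0 = total_reflectance(OpticalProperties(801, 0.0, 1.0), geometry)
        r_eps = total_reflectance(OpticalProperties(801, 1e-9, 1.0), geometry)
        assert r_eps == pytest.approx(r0, rel=1e-6)

    @pytest.mark.parametrize("mu_a,mu_sp", [(0.005, 0.7), (0.01, 1.0),
                                            (0.02, 1.3)])
    def test_matches_closed_form_integral(self, mu_a, mu_sp, geometry):
        """Quadrature agrees with the Bessel-K(3/2) closed-form integral."""
        optics = OpticalProperties(801, mu_a, mu_sp)
        assert total_reflectance(optics, geometry) == pytest.approx(
            stationary_reflectance(optics, geometry), rel=1e-7)

    def test_log_derivative_equals_closed_form_path_length(self, geometry):
        """-d ln(R_total)/d mu_a by central difference (step 1e-5) equals
        the analytic mean path length within 1%."""
        step = 1e-5
        up = np.log(total_reflectance(
            OpticalProperties(801, 0.01 + step, 1.0), geometry))
        dn = np.log(total_reflectance(
            OpticalProperties(801, 0.01 - step, 1.0), geometry))
        fd = -(up - dn) / (2 * step)
        analytic = mean_path_length_cw(
            OpticalProperties(801, 0.01, 1.0), geometry)
        assert fd == pytest.approx(analytic, rel=0.01)


class TestMeanTime:
    def test_symmetric_curve_centroid(self):
        axis = TimeAxis.regular(5, 10.0)
        curve = TPSFCurve(axis, [1, 2, 5, 2, 1])
        assert mean_time(curve) == pytest.approx(axis.centers[2])

    def test_single_bin(self):
        axis = TimeAxis.regular(10, 10.0)
        vals = np.zeros(10)
        vals[7] = 3.0
        assert mean_time(TPSFCurve(axis, vals)) == pytest.approx(
            axis.centers[7])

    def test_hand_weighted_mean(self):
        axis = TimeAxis(np.array([0.0, 200.0, 400.0]))  # centers 100, 300
        assert mean_time(TPSFCurve(axis, [1, 3])) == pytest.approx(250.0)

    def test_zero_area_curve_errors(self, axis):
        with pytest.raises(ValueError, match="zero-area"):
            mean_time(TPSFCurve(axis, np.zeros(axis.n_bins)))


def test_peak_time_monotonic_in_rho_and_scatter(axis):
    """Peak arrives later for larger separations and stronger scattering."""
    def peak(rho, mu_sp):
        curve = diffusion_reflectance(
            OpticalProperties(801, 0.01, mu_sp), ProbeGeometry(rho), axis)
        return axis.centers[np.argmax(curve.values)]

    peaks_rho = [peak(rho, 1.0) for rho in (15, 20, 25, 30, 35)]
    assert all(b >= a for a, b in zip(peaks_rho, peaks_rho[1:]))
    peaks_mus = [peak(30, m) for m in (0.4, 0.7, 1.0, 1.3)]
    assert all(b >= a for a, b in zip(peaks_mus, peaks_mus[1:]))


def test_time_axis_invariants():
    with pytest.raises(ValueError, match="at least 2 bins"):
        TimeAxis(np.array([0.0, 10.0]))
    with pytest.raises(ValueError, match="increasing"):
        TimeAxis(np.array([0.0, 10.0, 5.0]))
    with pytest.raises(ValueError, match="uniform"):
        TimeAxis(np.array([0.0, 10.0, 30.0]))
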