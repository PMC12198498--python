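"""Spline representation and forward integration of the kinetics ODE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import diffgek as dg
from diffgek.core import DomainError


def natural_spline_oracle(x, y, t):
    """Textbook natural cubic spline: tridiagonal solve for second derivatives.

    Independent of scipy's implementation; standard construction with
    M_0 = M_{n-1} = 0 boundary conditions.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    h = np.diff(x)
    # tridiagonal system A m = r for interior second derivatives
    A = np.zeros((n - 2, n - 2))
    r = np.zeros(n - 2)
    for i in range(1, n - 1):
        j = i - 1
        A[j, j] = 2.0 * (h[i - 1] + h[i])
        if j > 0:
            A[j, j - 1] = h[i - 1]
        if j < n - 3:
            A[j, j + 1] = h[i]
        r[j] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.zeros(n)
    m[1:-1] = np.linalg.solve(A, r)
    i = np.searchsorted(x, t, side="right") - 1
    i = min(max(i, 0), n - 2)
    d = t - x[i]
    return (
        y[i]
        + d * ((y[i + 1] - y[i]) / h[i] - h[i] * (2 * m[i] + m[i + 1]) / 6.0)
        + d**2 * m[i] / 2.0
        + d**3 * (m[i + 1] - m[i]) / (6.0 * h[i])
    )


class TestRateSpline:
    def test_constant_spline_is_constant_everywhere(self):
        sp = dg.RateSpline.constant(2.5)
        t = np.linspace(0, 1, 37)
        assert np.allclose(sp(t), 2.5, atol=1e-12)

    def test_interpolates_node_values_at_knots(self, rng):
        nt = dg.default_node_times()
        values = rng.uniform(0, dg.RATE_MAX, size=8)
        sp = dg.RateSpline(nt, values)
        assert np.allclose(sp(nt), values, atol=1e-10)

    def test_matches_independent_tridiagonal_construction(self):
        nt = dg.default_node_times()
        # quadratic node values scaled into the rate bound
        raw = np.array([0.0, 1.0, 4.0, 9.0, 16.0, 25.0, 36.0, 49.0])
        values = raw / 49.0 * dg.RATE_MAX
        sp = dg.RateSpline(nt, values)
        t_mid = 0.5 * (nt[1] + nt[2])
        expected = natural_spline_oracle(nt, values, t_mid)
        assert sp(t_mid) == pytest.approx(expected, rel=1e-10)

    def test_natural_boundary_second_derivative_zero(self):
        sp = dg.RateSpline(dg.default_node_times(), np.linspace(0.5, 6.0, 8))
        d2 = sp._spline.derivative(2)
        assert abs(d2(0.0)) < 1e-8 and abs(d2(1.0)) < 1e-8

    def test_out_of_domain_raises(self):
        sp = dg.RateSpline.constant(1.0)
        with pytest.raises(DomainError):
            sp(1.5)
        with pytest.raises(DomainError):
            dg.eval_spline(sp, -0.1)

    def test_undershoot_clipped_at_zero(self):
        # a sharp dip to the 0 bound makes the interpolant undershoot
        values = np.array([3.0, 0.0, 0.0, 3.0, 3.0, 0.0, 0.0, 3.0])
        sp = dg.RateSpline(dg.default_node_times(), values)
        t = np.linspace(0, 1, 501)
        assert np.all(sp(t) >= 0.0)
        raw = sp._spline(t)
        assert raw.min() < -1e-3  # clip actually did something

    def test_rejects_invalid_nodes(self):
        nt = dg.default_node_times()
        with pytest.raises(ValueError):
            dg.RateSpline(nt, np.full(8, dg.RATE_MAX + 1.0))
        with pytest.raises(ValueError):
            dg.RateSpline(nt[::-1], np.ones(8))


def closed_form_constant_rates(t, a, b, c, u0, s0):
    """Analytic solution of the constant-coefficient linear system."""
    tt = t - t[0]
    u = a / b + (u0 - a / b) * np.exp(-b * tt)
    A = a / c
    B = b * (u0 - a / b) / (c - b)
    s = A + B * np.exp(-b * tt) + (s0 - A - B) * np.exp(-c * tt)
    return u, s


class TestIntegrateKinetics:
    def test_constant_rates_match_two_exponential_closed_form(self):
        a, b, c, u0, s0 = 2.0, 1.0, 0.5, 0.0, 0.0
        kin = dg.KineticParams(
            dg.RateSpline.constant(a),
            dg.RateSpline.constant(b),
            dg.RateSpline.constant(c),
            u0,
            s0,
        )
        t = np.linspace(0, 1, 20)
        traj = dg.integrate_kinetics(kin, t)
        u_exact, s_exact = closed_form_constant_rates(t, a, b, c, u0, s0)
        scale_u = np.maximum(np.abs(u_exact), 1e-9)
        scale_s = np.maximum(np.abs(s_exact), 1e-9)
        assert np.max(np.abs(traj.u - u_exact) / scale_u) < 1e-6
        assert np.max(np.abs(traj.s - s_exact) / scale_s) < 1e-6

    def test_null_system_stays_zero(self):
        kin = dg.KineticParams(
            dg.RateSpline.constant(0.0),
            dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(0.5),
            0.0,
            0.0,
        )
        traj = dg.integrate_kinetics(kin, np.linspace(0, 1, 10))
        assert np.allclose(traj.u, 0.0, atol=1e-12)
        assert np.allclose(traj.s, 0.0, atol=1e-12)

    def test_steady_state_is_preserved(self):
        a, b, c = 2.0, 1.0, 0.5
        kin = dg.KineticParams(
            dg.RateSpline.constant(a),
            dg.RateSpline.constant(b),
            dg.RateSpline.constant(c),
            u0=a / b,
            s0=a / c,
        )
        traj = dg.integrate_kinetics(kin, np.linspace(0, 1, 15))
        assert np.allclose(traj.u, a / b, rtol=1e-6)
        assert np.allclose(traj.s, a / c, rtol=1e-6)

    @given(seed=st.integers(0, 2**20))
    def test_solution_nonnegative_for_nonnegative_inputs(self, seed):
        r = np.random.default_rng(seed)
        nt = dg.default_node_times()
        kin = dg.KineticParams(
            dg.RateSpline(nt, r.uniform(0, dg.RATE_MAX, 8)),
            dg.RateSpline(nt, r.uniform(0, dg.RATE_MAX, 8)),
            dg.RateSpline(nt, r.uniform(0, dg.RATE_MAX, 8)),
            u0=r.uniform(0, 5),
            s0=r.uniform(0, 5),
        )
        traj = dg.integrate_kinetics(kin, np.linspace(0, 1, 20))
        assert np.all(traj.u >= -1e-7)
        assert np.all(traj.s >= -1e-7)

    def test_mass_flow_monotonicity(self):
        nt = dg.default_node_times()
        # no degradation: total U+S cannot decrease
        kin = dg.KineticParams(
            dg.RateSpline.constant(1.5),
            dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(0.0),
            0.5,
            0.5,
        )
        traj = dg.integrate_kinetics(kin, np.linspace(0, 1, 30))
        assert np.all(np.diff(traj.u + traj.s) >= -1e-9)
        # no transcription: total U+S cannot increase
        kin2 = dg.KineticParams(
            dg.RateSpline.constant(0.0),
            dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(0.8),
            2.0,
            1.0,
        )
        traj2 = dg.integrate_kinetics(kin2, np.linspace(0, 1, 30))
        assert np.all(np.diff(traj2.u + traj2.s) <= 1e-9)

    def test_rejects_unordered_or_out_of_domain_times(self):
        kin = dg.KineticParams(
            dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(1.0),
            dg.RateSpline.constant(1.0),
            0.0,
            0.0,
        )
        with pytest.raises(ValueError):
            dg.integrate_kinetics(kin, np.array([0.5, 0.2]))
        with pytest.raises(DomainError):
            dg.integrate_kinetics(kin, np.array([0.0, 1.5]))
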