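"""Two-compartment electrotonics, clamp modes, and current reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import glusyn as g
from glusyn.neuron_electrotonics import (
    ClampSpec,
    cc_rhs,
    input_conductance,
    input_conductance_from_equations,
    mg_block_factor,
    one_compartment_rhs,
    reconstruct_dendritic_current,
    resting_vc,
    somatic_current_vc,
    synaptic_currents,
    vc_rhs,
)
from glusyn.params import ParameterError


class TestMgBlock:
    def test_no_magnesium_no_block(self):
        for v in (-100.0, 0.0, 50.0):
            assert mg_block_factor(v, 0.0) == 1.0

    def test_half_block_at_scale_concentration(self):
        assert mg_block_factor(0.0, 3.57) == pytest.approx(0.5, rel=1e-12)

    def test_hyperpolarized_block(self):
        expected = 1.0 / (1.0 + math.exp(0.062 * 80.0) / 3.57)
        assert mg_block_factor(-80.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_voltage(self):
        v = np.linspace(-100, 60, 200)
        f = mg_block_factor(v, 1.0)
        assert np.all(np.diff(f) > 0)


class TestSynapticCurrents:
    def test_reversal_and_zero_gates(self, receptor_params):
        ia, inn = synaptic_currents(0.3, 0.3, 0.0, receptor_params)  # U_rev = 0
        assert ia == 0.0 and inn == 0.0
        ia, inn = synaptic_currents(0.0, 0.0, -70.0, receptor_params)
        assert ia == 0.0 and inn == 0.0

    def test_nmda_current_hand_value(self):
        p = g.ReceptorParams(gbar_nmda=75.0, mg_out=1.0)
        f = 1.0 / (1.0 + math.exp(0.062 * 20.0) / 3.57)
        _, i_nmda = synaptic_currents(0.0, 0.1, -20.0, p)
        assert i_nmda == pytest.approx(75.0 * 0.1 * f * 20.0, rel=1e-12)


class TestCurrentClamp:
    def test_rest_is_fixed_point(self, neuron_params):
        dU, dUd = cc_rhs(neuron_params.U_L, neuron_params.U_L, 0.0, 0.0, neuron_params)
        assert dU == 0.0 and dUd == 0.0

    def test_missing_dendrite_rejects_dendritic_current(self):
        p = g.NeuronParams(gamma=0.0)
        with pytest.raises(ParameterError):
            cc_rhs(-70.0, -70.0, 10.0, 0.0, p)

    def test_gamma_zero_reduces_to_one_compartment(self):
        p = g.NeuronParams(gamma=0.0)
        dU, _ = cc_rhs(-60.0, -60.0, 0.0, 25.0, p)
        assert dU == pytest.approx(one_compartment_rhs(-60.0, 0.0, 25.0, p))

    @given(
        gamma=st.floats(min_value=0.2, max_value=6.0),
        l=st.floats(min_value=0.3, max_value=5.0),
        g_s=st.floats(min_value=2.0, max_value=20.0),
        i_inj=st.floats(min_value=-200.0, max_value=200.0),
    )
    def test_input_conductance_matches_steady_state(self, gamma, l, g_s, i_inj):
        """The equation-derived input conductance equals I_inj / (U - U_L) at
        the numerically solved steady state of the two-compartment system."""
        p = g.NeuronParams(gamma=gamma, l=l, G_s=g_s)
        # solve the 2x2 linear steady state directly
        A = np.array(
            [
                [-(1 + 2 * gamma / l), 2 * gamma / l],
                [2 / l, -(1 + 2 / l)],
            ]
        )
        b = np.array([-p.U_L - i_inj / g_s, -p.U_L])
        U, U_d = np.linalg.solve(A, b)
        dU, dUd = cc_rhs(U, U_d, 0.0, i_inj, p)
        assert abs(dU) < 1e-9 and abs(dUd) < 1e-9
        if abs(U - p.U_L) > 1e-3:
            assert i_inj / (U - p.U_L) == pytest.approx(
                input_conductance_from_equations(p), rel=1e-7
            )


@pytest.mark.parametrize(
    "gamma, factor", [(0.0, 1.0), (2.0, 1.4), (1e9, 2.0)]
)
def test_input_conductance_limits(gamma, factor):
    p = g.NeuronParams(gamma=gamma) if gamma > 0 else g.NeuronParams(gamma=0.0)
    assert input_conductance(p) == pytest.approx(factor * p.G_s, rel=1e-6)


class TestVoltageClamp:
    def test_resting_potential_values(self):
        p = g.NeuronParams(U_L=-70.0, l=2.0)
        assert resting_vc(p, -70.0) == pytest.approx(-70.0)
        assert resting_vc(p, 0.0) == pytest.approx(-35.0)
        p_long = g.NeuronParams(U_L=-70.0, l=1e9)
        assert resting_vc(p_long, 40.0) == pytest.approx(-70.0, rel=1e-6)

    def test_rest_is_fixed_point(self, neuron_params):
        for vh in (-80.0, -20.0, 40.0):
            assert vc_rhs(resting_vc(neuron_params, vh), 0.0, vh, neuron_params) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_effective_time_constant(self, neuron_params):
        """The dendritic relaxation rate in VC is (1 + 2/l) / tau_m."""
        vh = -60.0
        u0 = resting_vc(neuron_params, vh)
        delta = 1.0
        slope = vc_rhs(u0 + delta, 0.0, vh, neuron_params) - vc_rhs(u0, 0.0, vh, neuron_params)
        assert slope == pytest.approx(-(1 + 2 / neuron_params.l) / neuron_params.tau_m)

    def test_somatic_current_value_and_sign(self):
        p = g.NeuronParams(gamma=2.0, G_s=8.0, l=1.3)
        u0 = resting_vc(p, -80.0)
        assert somatic_current_vc(u0, -80.0, p) == 0.0
        assert somatic_current_vc(u0 + 1.0, -80.0, p) == pytest.approx(2 * 8.0 * 2.0 / 1.3)
        assert somatic_current_vc(u0 - 1.0, -80.0, p) == pytest.approx(-2 * 8.0 * 2.0 / 1.3)


class TestReconstruction:
    def test_constant_and_zero_traces(self, neuron_params):
        const = np.full(50, 7.0)
        out = reconstruct_dendritic_current(const, 0.1, neuron_params)
        np.testing.assert_allclose(out, (1 + neuron_params.l / 2) * 7.0, rtol=1e-12)
        np.testing.assert_allclose(
            reconstruct_dendritic_current(np.zeros(10), 0.1, neuron_params), 0.0
        )

    def test_short_trace_rejected(self, neuron_params):
        with pytest.raises(ValueError):
            reconstruct_dendritic_current(np.array([1.0, 2.0]), 0.1, neuron_params)

    def test_round_trip_recovers_dendritic_current(self, neuron_params):
        """Simulate the passive dendrite in VC under a known smooth I_d, then
        invert the clamp current; the reconstruction is exact for the linear
        cable up to finite-difference error."""
        vh = -80.0
        dt = 0.05
        t = np.arange(0.0, 120.0, dt)
        tau_a = 5.0
        i_d = 500.0 * (t / tau_a) * np.exp(1 - t / tau_a)
        sol = solve_ivp(
            lambda tt, y: [vc_rhs(y[0], np.interp(tt, t, i_d), vh, neuron_params)],
            (0, t[-1]),
            [resting_vc(neuron_params, vh)],
            t_eval=t,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        i_vc = somatic_current_vc(sol.y[0], vh, neuron_params)
        recovered = reconstruct_dendritic_current(i_vc, dt, neuron_params)
        err = np.max(np.abs(recovered - i_d)) / np.max(np.abs(i_d))
        assert err < 5e-3


class TestOneCompartment:
    def test_fixed_points(self, neuron_params):
        assert one_compartment_rhs(neuron_params.U_L, 0.0, 0.0, neuron_params) == 0.0
        i = 40.0
        u_inf = neuron_params.U_L + i / neuron_params.G_s
        assert one_compartment_rhs(u_inf, i, 0.0, neuron_params) == pytest.approx(0.0)


def test_two_compartment_matches_matrix_exponential(neuron_params):
    """Independent oracle: for piecewise-constant I_d the linear system has an
    exact matrix-exponential solution; the integrated equations must match it
    to 1e-6 relative."""
    p = neuron_params
    A = (
        np.array(
            [
                [-(1 + 2 * p.gamma / p.l), 2 * p.gamma / p.l],
                [2 / p.l, -(1 + 2 / p.l)],
            ]
        )
        / p.tau_m
    )
    segments = [(0.0, 20.0, 0.0), (20.0, 50.0, 300.0), (50.0, 90.0, -120.0)]
    y = np.array([p.U_L, p.U_L])
    y_exact = y.copy()
    for a, b, i_d in segments:
        # exact propagation over the segment
        bvec = np.array([p.U_L / p.tau_m, (p.U_L + i_d / (p.gamma * p.G_s)) / p.tau_m])
        y_inf = -np.linalg.solve(A, bvec)
        y_exact = y_inf + expm(A * (b - a)) @ (y_exact - y_inf)
        # integrated trajectory over the same segment
        sol = solve_ivp(
            lambda tt, yy: list(cc_rhs(yy[0], yy[1], i_d, 0.0, p)),
            (a, b),
            y,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        y = sol.y[:, -1]
    np.testing.assert_allclose(y, y_exact, rtol=1e-6)


def test_clamp_spec_validation():
    with pytest.raises(ParameterError):
        ClampSpec(mode="vc")  # V_h required
    with pytest.raises(ParameterError):
        ClampSpec(mode="cc", V_h=-80.0)  # V_h meaningless in CC
    with pytest.raises(ParameterError):
        ClampSpec(mode="ramp", V_h=0.0)
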