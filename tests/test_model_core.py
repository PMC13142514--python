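"""Membrane and synapse integrator: analytic fixed points, sign conventions,
and agreement with a high-accuracy adaptive reference integration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ca1ei.model import (SynapticState, nmdar_gate, simulate,
                         step_conductances, step_voltage, synaptic_current)
from ca1ei.params import ModelParams


# ---------------------------------------------------------------------------
# NMDAR voltage gate
# ---------------------------------------------------------------------------

class TestNmdarGate:
    def test_midpoint_is_half(self):
        assert nmdar_gate(-30.0, beta=0.08, v_half=-30.0) == pytest.approx(0.5)

    def test_limits(self):
        assert nmdar_gate(-1e4, 0.08, -30.0) == pytest.approx(0.0, abs=1e-12)
        assert nmdar_gate(1e4, 0.08, -30.0) == pytest.approx(1.0, abs=1e-12)

    def test_direct_evaluation(self):
        # 1/(1 + e^5) at beta=0.1, v_half=-50, v=-100
        assert nmdar_gate(-100.0, 0.1, -50.0) == pytest.approx(1.0 / (1.0 + math.e**5),
                                                               rel=1e-6)

    @given(st.floats(-90, 0), st.floats(-90, 0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, v1, v2):
        assume(abs(v1 - v2) > 1e-6)
        g1, g2 = nmdar_gate(v1, 0.08, -30.0), nmdar_gate(v2, 0.08, -30.0)
        if v1 < v2:
            assert g1 < g2
        else:
            assert g1 > g2
        assert 0.0 < g1 < 1.0


# ---------------------------------------------------------------------------
# synaptic currents
# ---------------------------------------------------------------------------

class TestSynapticCurrent:
    def test_zero_conductance(self):
        assert synaptic_current(0.0, -63.0, 0.0) == 0.0

    def test_zero_driving_force(self):
        assert synaptic_current(1e-3, -70.0, -70.0) == 0.0

    def test_excitatory_inward_is_negative(self):
        # below the 0 mV reversal, excitatory current is inward (negative)
        assert synaptic_current(1e-3, -63.0, 0.0) < 0

    def test_inhibitory_outward_above_reversal(self):
        assert synaptic_current(1e-3, -63.0, -70.0) > 0

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            synaptic_current(-1e-3, -63.0, 0.0)


# ---------------------------------------------------------------------------
# conductance dynamics
# ---------------------------------------------------------------------------

class TestConductanceStep:
    def test_zero_input_decays_exponentially(self):
        p = ModelParams()
        state = SynapticState(g_ampar=1.0, g_nmdar=1.0, g_gabar=1.0)
        out = step_conductances(state, {}, p)
        assert out.g_ampar == pytest.approx(math.exp(-p.dt / p.tau_ampar))
        assert out.g_nmdar == pytest.approx(math.exp(-p.dt / p.tau_nmdar))
        assert out.g_gabar == pytest.approx(math.exp(-p.dt / p.tau_gabar))

    def test_constant_drive_fixed_point(self):
        # g* = tau * g_unit * S (rates in Hz carry a 1e-3 Hz->1/ms factor)
        p = ModelParams()
        s = 2000.0
        state = SynapticState()
        for _ in range(20000):
            state = step_conductances(state, {"ampar": s, "nmdar": s, "gabar": s}, p)
        assert state.g_ampar == pytest.approx(p.tau_ampar * p.g_unit_ampar * s * 1e-3,
                                              rel=1e-6)
        assert state.g_nmdar == pytest.approx(p.tau_nmdar * p.g_unit_nmdar * s * 1e-3,
                                              rel=1e-6)

    def test_nmdar_decay_15x_slower_than_ampar(self):
        p = ModelParams()
        assert p.tau_nmdar / p.tau_ampar == pytest.approx(15.0)
        assert p.tau_gabar == p.tau_ampar

    def test_disabled_nmdar_stays_zero(self):
        p = ModelParams(nmdar_enabled=False)
        state = SynapticState(g_nmdar=0.0)
        for _ in range(10):
            state = step_conductances(state, {"nmdar": 5000.0}, p)
        assert state.g_nmdar == 0.0

    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=30)
    def test_nonnegative_for_arbitrary_inputs(self, rates):
        p = ModelParams()
        state = SynapticState()
        for r in rates:
            state = step_conductances(state, {"ampar": r, "nmdar": r, "gabar": r}, p)
            assert state.g_ampar >= 0 and state.g_nmdar >= 0 and state.g_gabar >= 0


# ---------------------------------------------------------------------------
# voltage dynamics
# ---------------------------------------------------------------------------

class TestVoltageStep:
    def test_relaxation_to_leak_with_tau_cell(self):
        p = ModelParams()
        state = SynapticState(v=-40.0)
        t, v0 = 0.0, -40.0
        for _ in range(200):
            state = step_voltage(state, p)
            t += p.dt
        expected = p.e_leak + (v0 - p.e_leak) * math.exp(-t / p.tau_cell)
        assert state.v == pytest.approx(expected, abs=0.05)

    def test_constant_current_fixed_point(self):
        # inward current I (depolarizing, negative sign): v* = e_leak + I*R
        p = ModelParams()
        i_inj = 0.05  # nA
        state = SynapticState()
        state.v = p.e_leak
        for _ in range(5000):
            state = step_voltage(state, p, i_inj=i_inj)
        assert state.v == pytest.approx(p.e_leak + i_inj * p.r_inp, rel=1e-6)

    def test_nan_aborts(self):
        p = ModelParams()
        state = SynapticState(g_ampar=1e6, v=1e300)
        with pytest.raises(FloatingPointError):
            for _ in range(10):
                state = step_voltage(state, p)


# ---------------------------------------------------------------------------
# vectorized path consistency and reference integration
# ---------------------------------------------------------------------------

def _sinusoid_rates(n, dt, base, amp, f_hz=7.0):
    t = np.arange(1, n + 1) * dt
    return base + amp * np.sin(2 * np.pi * f_hz * t / 1000.0)


class TestVectorizedPath:
    def test_matches_step_functions(self):
        p = ModelParams()
        n = 400
        rates = {k: _sinusoid_rates(n, p.dt, 2000.0, 500.0) for k in
                 ("ampar", "nmdar", "gabar")}
        out = simulate(rates, p)
        state = SynapticState(v=p.e_leak)
        for i in range(n):
            state = step_conductances(state, {k: rates[k][i] for k in rates}, p)
            state = step_voltage(state, p)
            assert state.g_ampar == pytest.approx(out["g_ampar"][i], rel=1e-12)
            assert state.g_nmdar == pytest.approx(out["g_nmdar"][i], rel=1e-12)
            assert state.g_gabar == pytest.approx(out["g_gabar"][i], rel=1e-12)
            assert state.v == pytest.approx(out["v"][i], abs=1e-9)

    def test_disabled_nmdar_identical_to_zero_unit(self):
        n = 2000
        rates = {k: _sinusoid_rates(n, 0.5, 2000.0, 800.0) for k in
                 ("ampar", "nmdar", "gabar")}
        p_off = ModelParams(nmdar_enabled=False, g_unit_nmdar=3e-4)
        p_zero = ModelParams(nmdar_enabled=True, g_unit_nmdar=0.0)
        v_off = simulate(rates, p_off)["v"]
        v_zero = simulate(rates, p_zero)["v"]
        assert np.array_equal(v_off, v_zero)

    def test_voltage_bounded_by_reversals(self):
        n = 4000
        rng = np.random.default_rng(0)
        rates = {k: rng.uniform(0, 5000, n) for k in ("ampar", "nmdar", "gabar")}
        p = ModelParams()
        v = simulate(rates, p)["v"]
        assert v.min() >= min(p.e_gabar, p.e_leak) - 1e-9
        assert v.max() <= max(p.e_ampar, p.e_leak) + 1e-9


class TestReferenceIntegration:
    def _reference(self, rates_fn, p, t_end):
        """Adaptive fine-tolerance integration of the continuous equations."""

        def rhs(t, y):
            ga, gn, gg, v = y
            gate = 1.0 / (1.0 + math.exp(-p.beta * (v - p.v_half)))
            i_syn = ga * (v - p.e_ampar) + gn * gate * (v - p.e_nmdar) \
                + gg * (v - p.e_gabar)
            s = rates_fn(t)
            return [-ga / p.tau_ampar + p.g_unit_ampar * s * 1e-3,
                    -gn / p.tau_nmdar + p.g_unit_nmdar * s * 1e-3,
                    -gg / p.tau_gabar + p.g_unit_gabar * s * 1e-3,
                    (-(v - p.e_leak) - i_syn * p.r_inp) / p.tau_cell]

        sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0, 0.0, p.e_leak],
                        rtol=1e-10, atol=1e-12, dense_output=True, max_step=0.5)
        return sol.sol

    def test_agreement_with_fine_step_oracle(self):
        """The dt = 0.1·tau_ampar discretization tracks the adaptive reference
        within 0.05 mV on a smooth theta-modulated drive."""
        p = ModelParams(dt=0.5)
        base, amp = 2000.0, 800.0

        def rates_fn(t):
            return base + amp * np.sin(2 * np.pi * 7.0 * t / 1000.0)

        t_end = 1000.0
        n = int(t_end / p.dt)
        rates = {k: rates_fn(np.arange(1, n + 1) * p.dt - p.dt / 2.0)
                 for k in ("ampar", "nmdar", "gabar")}
        v = simulate(rates, p)["v"]
        ref = self._reference(rates_fn, p, t_end)
        t_grid = np.arange(1, n + 1) * p.dt
        v_ref = ref(t_grid)[3]
        err = np.abs(v - v_ref)[200:]  # past the initial conductance transient
        assert err.max() < 0.05

    def test_halving_dt_changes_trace_below_tolerance(self):
        base, amp = 2000.0, 800.0

        def make(dt):
            p = ModelParams(dt=dt)
            n = int(1000.0 / dt)
            t = np.arange(1, n + 1) * dt - dt / 2.0
            s = base + amp * np.sin(2 * np.pi * 7.0 * t / 1000.0)
            return simulate({k: s for k in ("ampar", "nmdar", "gabar")}, p)["v"]

        v_c = make(0.5)
        v_f = make(0.25)[1::2]
        assert np.abs(v_c - v_f).max() < 0.1
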