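"""Single-compartment membrane equation with AMPAR, NMDAR and GABAR synapses.

The membrane evolves as

    τ_cell · dV/dt = −(V − E_leak) − I_syn · R_inp

with I_syn = I_AMPAR + I_NMDAR + I_GABAR and, per convention, excitatory
inward (depolarizing) currents negative. Each synaptic current is
I_X = g_X · (V − E_X); the NMDAR current carries an extra sigmoidal
voltage-dependent factor approximating the Mg²⁺ block. Conductances follow

    dg_X/dt = −g_X/τ_X + g_unit,X · Σ_i w_i,X · r_i

driven by weighted presynaptic rate sums.

Discretization (one canonical scheme used by both the step-function API and
the vectorized fast path, so the two are bit-identical):

1. exponential Euler for each conductance — exact decay plus the forced term
   with the rate sum held constant over the step:
   g[n+1] = a·g[n] + (1−a)·τ·g_unit·S[n]·1e-3,  a = exp(−dt/τ)
   (the 1e-3 converts presynaptic rates in Hz to 1/ms);
2. forward Euler for the voltage using the *updated* conductances:
   V[n+1] = V[n] + dt/τ_cell · (−(V[n]−E_leak) − I_syn(V[n], g[n+1])·R_inp).

An extrinsic injected current ``i_inj`` (nA, positive = depolarizing) enters
additively with I_syn as an inward (negative-sign) current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .params import ModelParams

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def nmdar_gate(v, beta, v_half):
    """Sigmoidal voltage dependence of the NMDAR conductance (Mg²⁺ block).

    Returns 1/(1 + exp(−β·(v − v_half))) ∈ (0, 1), strictly increasing in v.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return 1.0 / (1.0 + np.exp(-beta * (np.asarray(v, dtype=float) - v_half)))


def synaptic_current(g, v, e_rev, gate=1.0):
    """I = g·gate·(V − E_rev) in nA (g in µS, voltages in mV).

    With E_rev = 0 and V < 0 the result is negative: excitatory inward
    currents are depolarizing and carry a negative sign.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("negative conductance: corrupted synaptic state")
    return g * gate * (np.asarray(v, dtype=float) - e_rev)


@dataclass
class SynapticState:
    """Instantaneous conductances (µS) and membrane voltage (mV)."""

    g_ampar: float = 0.0
    g_nmdar: float = 0.0
    g_gabar: float = 0.0
    v: float = -63.0


def step_conductances(state: SynapticState, rate_sums: dict, p: ModelParams,
                      dt: float | None = None) -> SynapticState:
    """One exponential-Euler step of all three conductances.

    ``rate_sums`` maps 'ampar'/'nmdar'/'gabar' to the weighted presynaptic
    rate sum Σ w·r in Hz for that synapse type.
    """
    dt = p.dt if dt is None else dt
    out = SynapticState(v=state.v)
    for name, tau, gu in (("ampar", p.tau_ampar, p.g_unit_ampar),
                          ("nmdar", p.tau_nmdar, p.g_unit_nmdar),
                          ("gabar", p.tau_gabar, p.g_unit_gabar)):
        s = float(rate_sums.get(name, 0.0))
        if s < 0:
            raise ValueError("presynaptic rate sums must be non-negative")
        a = math.exp(-dt / tau)
        g = getattr(state, f"g_{name}")
        if name == "nmdar" and not p.nmdar_enabled:
            gnew = 0.0
        else:
            gnew = a * g + (1.0 - a) * tau * gu * s * 1e-3
        setattr(out, f"g_{name}", gnew)
    return out


def step_voltage(state: SynapticState, p: ModelParams, i_inj: float = 0.0,
                 dt: float | None = None) -> SynapticState:
    """One forward-Euler voltage step given the (already updated) conductances."""
    dt = p.dt if dt is None else dt
    v = state.v
    gate = nmdar_gate(v, p.beta, p.v_half) if p.nmdar_enabled else 0.0
    i_syn = (state.g_ampar * (v - p.e_ampar)
             + state.g_nmdar * gate * (v - p.e_nmdar)
             + state.g_gabar * (v - p.e_gabar)
             - i_inj)
    v_new = v + dt / p.tau_cell * (-(v - p.e_leak) - i_syn * p.r_inp)
    if not math.isfinite(v_new):
        raise FloatingPointError("non-finite membrane voltage: aborting trial")
    return SynapticState(state.g_ampar, state.g_nmdar, state.g_gabar, v_new)


# ---------------------------------------------------------------------------
# vectorized fast path
# ---------------------------------------------------------------------------

def integrate_conductance(rate_sum: np.ndarray, tau: float, g_unit: float,
                          dt: float, g0: float = 0.0) -> np.ndarray:
    """Exponential-Euler conductance trace for a whole rate-sum series.

    Returns g[n+1] for n = 0..N-1 (the value *after* each step), matching
    repeated calls to :func:`step_conductances` from g(0) = g0.
    """
    a = math.exp(-dt / tau)
    b = (1.0 - a) * tau * g_unit * 1e-3
    zi = np.array([a * g0])
    y, _ = lfilter([b], [1.0, -a], np.asarray(rate_sum, dtype=float), zi=zi)
    return y


@njit(cache=True, fastmath=True)
def _voltage_loop(g_a, g_n, g_g, e_leak, e_ampar, e_nmdar, e_gabar,
                  beta, v_half, r_inp, tau_cell, dt, i_inj, v0, use_gate):
    n = g_a.shape[0]
    v = np.empty(n)
    vv = v0
    for i in range(n):
        if use_gate:
            gate = 1.0 / (1.0 + math.exp(-beta * (vv - v_half)))
        else:
            gate = 0.0
        i_syn = (g_a[i] * (vv - e_ampar) + g_n[i] * gate * (vv - e_nmdar)
                 + g_g[i] * (vv - e_gabar) - i_inj)
        vv = vv + dt / tau_cell * (-(vv - e_leak) - i_syn * r_inp)
        v[i] = vv
    return v


def integrate_voltage(g_a, g_n, g_g, p: ModelParams, i_inj: float = 0.0,
                      v0: float | None = None) -> np.ndarray:
    """Forward-Euler voltage trace over precomputed conductance series.

    Conductance arrays are the post-step values g[n+1], as produced by
    :func:`integrate_conductance`; the voltage update at step n therefore
    uses them directly, matching the step-function API.
    """
    v0 = p.e_leak if v0 is None else v0
    v = _voltage_loop(np.ascontiguousarray(g_a), np.ascontiguousarray(g_n),
                      np.ascontiguousarray(g_g),
                      p.e_leak, p.e_ampar, p.e_nmdar, p.e_gabar,
                      p.beta, p.v_half, p.r_inp, p.tau_cell, p.dt,
                      float(i_inj), float(v0), p.nmdar_enabled)
    if not np.isfinite(v[-1]):
        raise FloatingPointError("non-finite membrane voltage: aborting trial")
    return v


def simulate(rate_sums: dict, p: ModelParams, i_inj: float = 0.0,
             v0: float | None = None) -> dict:
    """Integrate the full model over rate-sum series; returns traces.

    ``rate_sums`` maps 'ampar'/'nmdar'/'gabar' to Σ w·r series in Hz. The
    NMDAR drive is ignored when ``p.nmdar_enabled`` is False (weights set
    to 0), making the trace bit-identical to g_unit_nmdar = 0.
    """
    n = len(next(iter(rate_sums.values())))
    zeros = np.zeros(n)
    g_a = integrate_conductance(rate_sums.get("ampar", zeros), p.tau_ampar,
                                p.g_unit_ampar, p.dt)
    if p.nmdar_enabled:
        g_n = integrate_conductance(rate_sums.get("nmdar", zeros), p.tau_nmdar,
                                    p.g_unit_nmdar, p.dt)
    else:
        g_n = zeros
    g_g = integrate_conductance(rate_sums.get("gabar", zeros), p.tau_gabar,
                                p.g_unit_gabar, p.dt)
    v = integrate_voltage(g_a, g_n, g_g, p, i_inj=i_inj, v0=v0)
    return {"v": v, "g_ampar": g_a, "g_nmdar": g_n, "g_gabar": g_g}
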