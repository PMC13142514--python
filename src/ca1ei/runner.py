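"""Simulation orchestration: variants, instances, trials and perturbations.

A *variant* is one of six model configurations: {uniform, balanced,
reciprocal} inhibition × NMDARs {on, off}. A :class:`SimContext` bundles
everything reusable across candidate parameter sets for one variant — the
trajectory, the CA3 drive basis, and per-instance connectomes with their
summed inhibitory rate profiles and per-trial LFP phase offsets. Candidate
evaluation then only assembles drive sums, filters them into conductances,
and integrates the voltage.

Perturbation protocols
  * control — nothing applied;
  * reduced inhibition — every GABAR conductance scaled by a fixed factor
    (0.5 by default) at every time step, mimicking optogenetic suppression
    of interneurons;
  * depolarized — a sustained extrinsic current ``i_inj`` (nA, positive =
    depolarizing) calibrated to drive the out-of-field voltage to a target,
    mimicking optogenetic depolarization of the place cell.

Neither perturbation touches the connectome or the input rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import features as feat
from .connectivity import Connectome, sample_inhibitory_connections, summed_inhibitory_rate
from .inputs import (Ca3DriveBasis, Ca3Population, InterneuronPopulation,
                     LfpReference, Trajectory, floor_gaussian)
from .model import integrate_conductance, integrate_voltage
from .params import ModelParams, StudyConfig

SCHEMES = ("uniform", "balanced", "reciprocal")


@dataclass(frozen=True)
class Variant:
    scheme: str
    nmdar: bool

    @property
    def label(self) -> str:
        return f"{self.scheme}_{'nmdar' if self.nmdar else 'ampar'}"


@dataclass
class CandidateParams:
    """The free parameters explored per model variant."""

    delta_w_ampar: float = 2.0
    g_unit_ampar: float = 8e-5
    g_unit_nmdar: float = 4e-5
    g_unit_gabar: float = 2e-4
    beta: float = 0.08
    v_half: float = -30.0
    phi_ca3: float = 180.0
    phi_inh: float = 180.0
    e_leak: float = -63.0

    def model_params(self, cfg: StudyConfig, nmdar: bool,
                     inhibition_scale: float = 1.0) -> ModelParams:
        return ModelParams(
            e_leak=self.e_leak,
            g_unit_ampar=self.g_unit_ampar,
            g_unit_nmdar=self.g_unit_nmdar if nmdar else 0.0,
            g_unit_gabar=self.g_unit_gabar * inhibition_scale,
            beta=self.beta, v_half=self.v_half,
            nmdar_enabled=nmdar, dt=cfg.dt)


@dataclass
class Protocol:
    condition: str = "control"          # control | reduced_inhibition | depolarized
    inhibition_scale: float = 1.0
    i_inj: float = 0.0                  # nA, positive = depolarizing

    def __post_init__(self):
        if not 0.0 < self.inhibition_scale <= 1.0:
            raise ValueError("inhibition_scale must be in (0, 1]")

    @classmethod
    def control(cls):
        return cls("control")

    @classmethod
    def reduced_inhibition(cls, scale=0.5):
        return cls("reduced_inhibition", inhibition_scale=scale)

    @classmethod
    def depolarized(cls, i_inj):
        return cls("depolarized", i_inj=i_inj)


@dataclass
class SimBatch:
    """Voltage traces of all trials of one condition, plus trial metadata."""

    cfg: StudyConfig
    condition: str
    variant: Variant
    field_center: float
    t_ms: np.ndarray
    x: np.ndarray
    analysis: slice
    vs: list
    phi_offsets: list
    i_inj: float = 0.0
    inhibition_scale: float = 1.0
    gs: list | None = None

    def to_frame(self, trial: int = 0) -> pd.DataFrame:
        """Columnar time series of one trial for inspection/serialization."""
        lfp = LfpReference(self.cfg.f_lfp, self.phi_offsets[trial])
        data = {"t_ms": self.t_ms, "x": self.x, "v": self.vs[trial],
                "lfp_phase": lfp.phase(self.t_ms)}
        if self.gs is not None:
            g_a, g_n, g_g = self.gs[trial]
            v = self.vs[trial]
            data.update(g_ampar=g_a, g_nmdar=g_n, g_gabar=g_g,
                        i_ampar=g_a * v, i_gabar=g_g * (v + 70.0))
        data["i_ext"] = np.full(len(self.t_ms), -self.i_inj)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# context
# ---------------------------------------------------------------------------

_BASIS_CACHE: dict = {}


def _basis_key(cfg: StudyConfig):
    return (cfg.track_length, cfg.speed, cfg.dt, cfg.n_steps, cfg.f_lfp,
            cfg.n_ca3, cfg.ca3_peak_rate, cfg.ca3_floor_width, cfg.d_ca3,
            cfg.k_ca3, cfg.field_center, cfg.ampar_floor_width)


class SimContext:
    """Reusable per-variant simulation state.

    Holds the trajectory, the (globally cached) CA3 harmonic drive basis,
    the calibrated interneuron populations, and per-instance connectomes,
    summed inhibitory rate profiles and trial phase offsets, all derived
    deterministically from one master seed.
    """

    def __init__(self, cfg: StudyConfig, variant: Variant, seed: int,
                 n_instances: int | None = None, n_trials: int | None = None):
        cfg.validate()
        self.cfg = cfg
        self.variant = variant
        self.seed = int(seed)
        self.n_instances = cfg.n_instances if n_instances is None else n_instances
        self.n_trials = cfg.n_trials if n_trials is None else n_trials
        self.traj = Trajectory.from_config(cfg)
        self.ca3 = Ca3Population.from_config(cfg)
        self.inh_pops = [InterneuronPopulation.calibrated("positive", cfg),
                         InterneuronPopulation.calibrated("negative", cfg)]

        key = _basis_key(cfg)
        if key not in _BASIS_CACHE:
            fld = floor_gaussian(self.ca3.centers, cfg.field_center,
                                 cfg.ampar_floor_width, cfg.track_length)
            _BASIS_CACHE[key] = Ca3DriveBasis(
                self.traj, self.ca3, cfg.f_lfp,
                {"base": np.ones(cfg.n_ca3), "field": fld})
        self.basis: Ca3DriveBasis = _BASIS_CACHE[key]

        theta_rad = np.deg2rad(360.0 * cfg.f_lfp * self.traj.t_ms / 1000.0)
        self._cos_theta = np.cos(theta_rad)
        self._sin_theta = np.sin(theta_rad)

        ss = np.random.SeedSequence([self.seed, 0xCA1E])
        inst_seeds = ss.spawn(self.n_instances)
        self.connectomes: list[Connectome] = []
        self.inh_profiles: list[np.ndarray] = []   # summed A(x(t)) over full grid
        self.phi_offsets: list[list[float]] = []
        lap = cfg.lap_steps
        x_lap = self.traj.x[:lap]
        reps = int(np.ceil(cfg.n_steps / lap))
        for iseed in inst_seeds:
            child = np.random.default_rng(iseed)
            conn_seed = int(child.integers(2**31))
            conn = sample_inhibitory_connections(
                variant.scheme, self.inh_pops, cfg.field_center,
                cfg.n_inh_connections, conn_seed,
                pref_floor_width=cfg.pref_floor_width)
            a_lap = summed_inhibitory_rate(conn, self.inh_pops, x_lap)
            a_full = np.tile(a_lap, reps)[:cfg.n_steps]
            offsets = [float(child.uniform(0.0, 360.0)) for _ in range(self.n_trials)]
            self.connectomes.append(conn)
            self.inh_profiles.append(a_full)
            self.phi_offsets.append(offsets)

    # -- drive assembly ----------------------------------------------------

    def rate_sums(self, instance: int, trial: int, cand: CandidateParams,
                  nmdar: bool | None = None) -> dict:
        """Weighted presynaptic rate sums (Hz) for one trial."""
        cfg = self.cfg
        nmdar = self.variant.nmdar if nmdar is None else nmdar
        phi_off = self.phi_offsets[instance][trial]
        phi_eff = cand.phi_ca3 - phi_off
        s_base = self.basis.summed_drive("base", phi_eff, cfg.d_ca3)
        s_field = self.basis.summed_drive("field", phi_eff, cfg.d_ca3)
        s_ampar = s_base + cand.delta_w_ampar * s_field
        s_nmdar = s_base if nmdar else np.zeros_like(s_base)
        # M_inh expanded over cached theta trig: same quantity as
        # inh_temporal_modulation, assembled without recomputing cos(2pi f t)
        delta = np.deg2rad(phi_off - cand.phi_inh)
        m_inh = (1.0 - cfg.d_inh / 2.0) + (cfg.d_inh / 2.0) * (
            self._cos_theta * np.cos(delta) - self._sin_theta * np.sin(delta))
        s_gabar = m_inh * self.inh_profiles[instance]
        return {"ampar": s_ampar, "nmdar": s_nmdar, "gabar": s_gabar}

    def conductances(self, instance: int, trial: int, cand: CandidateParams,
                     inhibition_scale: float = 1.0):
        """Conductance traces for one trial (independent of e_leak / i_inj)."""
        cfg = self.cfg
        p = cand.model_params(cfg, self.variant.nmdar, inhibition_scale)
        s = self.rate_sums(instance, trial, cand)
        g_a = integrate_conductance(s["ampar"], p.tau_ampar, p.g_unit_ampar, p.dt)
        if p.nmdar_enabled and p.g_unit_nmdar > 0:
            g_n = integrate_conductance(s["nmdar"], p.tau_nmdar, p.g_unit_nmdar, p.dt)
        else:
            g_n = np.zeros_like(g_a)
        g_g = integrate_conductance(s["gabar"], p.tau_gabar, p.g_unit_gabar, p.dt)
        return g_a, g_n, g_g

    def prepare_instance(self, instance: int, cand: CandidateParams,
                         inhibition_scale: float = 1.0) -> list:
        """Per-trial conductances, reusable across e_leak / i_inj values."""
        return [self.conductances(instance, tr, cand, inhibition_scale)
                for tr in range(self.n_trials)]

    @property
    def analysis(self) -> slice:
        return slice(self.cfg.lap_steps, self.cfg.n_laps * self.cfg.lap_steps)

    # -- running conditions ------------------------------------------------

    def batch_from_prep(self, prep: list, cand: CandidateParams,
                        protocol: Protocol, instance: int,
                        keep_conductances: bool = False) -> SimBatch:
        cfg = self.cfg
        p = cand.model_params(cfg, self.variant.nmdar, protocol.inhibition_scale)
        vs = [integrate_voltage(g_a, g_n, g_g, p, i_inj=protocol.i_inj)
              for (g_a, g_n, g_g) in prep]
        return SimBatch(cfg, protocol.condition, self.variant, cfg.field_center,
                        self.traj.t_ms, self.traj.x, self.analysis, vs,
                        list(self.phi_offsets[instance]),
                        i_inj=protocol.i_inj,
                        inhibition_scale=protocol.inhibition_scale,
                        gs=prep if keep_conductances else None)

    def run_condition(self, cand: CandidateParams, protocol: Protocol,
                      instance: int = 0, keep_conductances: bool = False) -> SimBatch:
        """Simulate all trials of one condition for one network instance."""
        prep = self.prepare_instance(instance, cand, protocol.inhibition_scale)
        return self.batch_from_prep(prep, cand, protocol, instance,
                                    keep_conductances=keep_conductances)


# ---------------------------------------------------------------------------
# calibrations
# ---------------------------------------------------------------------------

def _vm_out_for(ctx: SimContext, prep: list, cand: CandidateParams,
                e_leak: float, i_inj: float, instance: int) -> float:
    trial_cand = replace(cand, e_leak=e_leak)
    batch = ctx.batch_from_prep(prep, trial_cand, Protocol("control", i_inj=i_inj),
                                instance)
    return feat.ramp_extract(batch)["vm_out"]


def calibrate_e_leak(ctx: SimContext, cand: CandidateParams,
                     target_vm: float = -63.0, tol: float = 0.2,
                     bracket: tuple = (-90.0, -45.0), instance: int = 0,
                     max_iter: int = 60) -> float:
    """Find the leak reversal enforcing a target out-of-field Vm.

    Bisection on the trial-averaged, low-pass out-of-field voltage, which is
    continuous and strictly increasing in e_leak. The synaptic conductance
    traces do not depend on e_leak, so only the voltage integration reruns.
    """
    prep = ctx.prepare_instance(instance, cand)
    lo, hi = bracket
    f_lo = _vm_out_for(ctx, prep, cand, lo, 0.0, instance) - target_vm
    f_hi = _vm_out_for(ctx, prep, cand, hi, 0.0, instance) - target_vm
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"e_leak bracket {bracket} does not bracket the target "
            f"({f_lo + target_vm:.2f}, {f_hi + target_vm:.2f} mV)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _vm_out_for(ctx, prep, cand, mid, 0.0, instance) - target_vm
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("e_leak calibration did not converge")


def calibrate_holding_current(ctx: SimContext, cand: CandidateParams,
                              target_out_vm: float, tol: float = 0.2,
                              max_eval: int = 30, instance: int = 0) -> float:
    """Extrinsic current (nA, >= 0) driving out-of-field Vm to a target.

    Out-of-field Vm increases monotonically with the depolarizing current;
    an initial passive estimate ΔV·(1 + R·g_tot)/R brackets the root, then
    bisection refines it to within ``tol`` mV.
    """
    prep = ctx.prepare_instance(instance, cand)
    n_eval = 0

    def vm_out(i_inj):
        nonlocal n_eval
        n_eval += 1
        return _vm_out_for(ctx, prep, cand, cand.e_leak, i_inj, instance)

    v0 = vm_out(0.0)
    dv = target_out_vm - v0
    if dv <= tol:
        return 0.0
    # passive slope estimate from mean total conductance
    g_tot = np.mean([g_a.mean() + g_n.mean() + g_g.mean() for g_a, g_n, g_g in prep])
    p = cand.model_params(ctx.cfg, ctx.variant.nmdar)
    i_hi = max(dv * (1.0 + p.r_inp * g_tot) / p.r_inp, 1e-4)
    while vm_out(i_hi) < target_out_vm:
        i_hi *= 2.0
        if n_eval >= max_eval:
            raise RuntimeError("holding-current calibration budget exhausted")
    i_lo = 0.0
    while n_eval < max_eval:
        mid = 0.5 * (i_lo + i_hi)
        v = vm_out(mid)
        if abs(v - target_out_vm) < tol:
            return mid
        if v < target_out_vm:
            i_lo = mid
        else:
            i_hi = mid
    raise RuntimeError("holding-current calibration did not converge")
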