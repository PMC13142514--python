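"""Configuration containers for the CA1 place-cell model study.

Two layers of configuration are kept separate:

* :class:`ModelParams` — biophysical constants of the single-compartment
  membrane equation and its three synapse types (AMPAR, NMDAR, GABAR).
* :class:`StudyConfig` — everything that defines the simulated experiment:
  the circular track, the LFP-like theta reference, the presynaptic
  populations, connectivity, trial structure and measurement windows.

Both can be loaded from / dumped to YAML so that a run is fully described
by one declarative file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class ModelParams:
    """Constants of the membrane and synaptic conductance equations.

    Units: time constants in ms, voltages in mV, input resistance in MΩ,
    unitary conductances in µS per (presynaptic Hz · ms). With conductance
    in µS, voltage in mV and resistance in MΩ, the product g·V is a current
    in nA and I·R is a voltage in mV, so no unit conversion constants appear
    in the integrator except the Hz→1/ms factor applied to input rates.
    """

    tau_cell: float = 20.0      # membrane time constant (ms)
    r_inp: float = 100.0        # input resistance (MΩ)
    e_leak: float = -63.0       # leak reversal (mV); calibrated or optimized
    e_ampar: float = 0.0        # AMPAR reversal (mV)
    e_nmdar: float = 0.0        # NMDAR reversal (mV)
    e_gabar: float = -70.0      # GABAR reversal (mV)
    tau_ampar: float = 5.0      # AMPAR decay (ms)
    tau_nmdar: float = 75.0     # NMDAR decay (ms)
    tau_gabar: float = 5.0      # GABAR decay (ms)
    g_unit_ampar: float = 8e-5  # unitary conductance scales (µS·ms·Hz⁻¹·1e-3)
    g_unit_nmdar: float = 4e-5
    g_unit_gabar: float = 2e-4
    beta: float = 0.08          # NMDAR sigmoid slope (1/mV)
    v_half: float = -30.0       # NMDAR sigmoid half-activation (mV)
    nmdar_enabled: bool = True
    dt: float = 0.5             # integration step (ms)

    def validate(self) -> None:
        for name in ("tau_cell", "tau_ampar", "tau_nmdar", "tau_gabar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_inp <= 0:
            raise ValueError("r_inp must be positive")
        if not (self.e_gabar < self.e_leak < self.e_ampar):
            raise ValueError("require e_gabar < e_leak < e_ampar")
        if self.dt > min(self.tau_ampar, self.tau_nmdar, self.tau_gabar):
            raise ValueError("dt must not exceed the smallest synaptic tau")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass
class StudyConfig:
    """Declarative description of the simulated treadmill experiment."""

    # track and trajectory
    track_length: float = 200.0     # cm, circular
    speed: float = 25.0             # cm/s, constant running speed
    dt: float = 0.5                 # ms, sampling/integration step
    n_laps: int = 3                 # total laps; the first is warm-up
    tail_pad_s: float = 2.0         # extra run-out so end windows are clean

    # LFP-like theta reference
    f_lfp: float = 7.0              # Hz

    # CA3 place-cell population
    n_ca3: int = 1000
    ca3_peak_rate: float = 25.0     # Hz at field center
    ca3_floor_width: float = 60.0   # cm; rate is exactly 0 beyond half-width
    d_ca3: float = 0.7              # theta modulation depth
    k_ca3: float = 0.7              # phase-tuning sharpness

    # interneuron subpopulations (one positively, one negatively tuned)
    n_inh_per_pop: int = 500
    inh_floor_width: float = 60.0
    inh_mean_rate: float = 25.0     # Hz, spatial mean after calibration
    d_inh: float = 0.5
    pos_peak_to_baseline: float = 47.7 / 21.3  # shape of the positive tuning

    # CA1 place field and connectivity
    field_center: float = 100.0     # cm
    ampar_floor_width: float = 60.0 # cm, width of the AMPAR weight profile
    pref_floor_width: float = 200.0 # cm, connectivity-preference width
    n_inh_connections: int = 300    # expected total inhibitory connections

    # trial structure
    n_trials: int = 5
    n_instances: int = 5
    inhibition_scale: float = 0.5   # GABAR scaling for the reduced-inh protocol

    # measurement
    window_s: float = 0.4           # in/out averaging window
    precession_window_s: float = 4.0
    out_field_distance: float = 60.0  # cm; "out-of-field" for phase pooling
    position_bin: float = 5.0       # cm, phase-vs-position binning
    lowpass_hz: float = 2.0
    band_low_hz: float = 4.0
    band_high_hz: float = 10.0
    feature_decimation: int = 4     # analyze Vm at dt*decimation (500 Hz);
                                    # theta-band content is far below Nyquist

    @property
    def lap_duration_s(self) -> float:
        return self.track_length / self.speed

    @property
    def lap_steps(self) -> int:
        return int(round(self.lap_duration_s * 1000.0 / self.dt))

    @property
    def n_steps(self) -> int:
        return self.n_laps * self.lap_steps + int(round(self.tail_pad_s * 1000.0 / self.dt))

    def validate(self) -> None:
        if self.track_length <= 0 or self.speed <= 0:
            raise ValueError("track_length and speed must be positive")
        if self.ca3_floor_width > self.track_length:
            raise ValueError("floor width cannot exceed track length")
        if not 0 < self.inhibition_scale <= 1:
            raise ValueError("inhibition_scale must be in (0, 1]")
        if self.n_laps < 2:
            raise ValueError("need at least one analysis lap after warm-up")

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
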