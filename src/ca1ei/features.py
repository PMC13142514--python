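"""Place-field feature extraction from intracellular voltage traces.

The measurements mirror standard in vivo intracellular analyses:

* the slow subthreshold ramp is isolated with a zero-phase low-pass filter
  (<2 Hz), trial-averaged, and summarized by means within 0.4 s windows
  centered on the place-field peak (in-field) and on the position
  diametrically opposite it (out-of-field);
* the intracellular theta oscillation is isolated with a zero-phase 4–10 Hz
  band-pass filter; its envelope is the magnitude of the analytic signal
  (Hilbert transform), trial-averaged and windowed the same way;
* theta phase precession is quantified from the peaks of the band-passed
  single-trial traces: each peak is assigned the LFP reference phase and the
  track position at its time, peaks are pooled across trials into a
  phase-versus-position map (circular mean per position bin), and the extent
  of precession is the unwrapped phase drop across a 4 s window surrounding
  the field peak;
* excitability is summarized by the least-squares slope of ramp amplitude
  against out-of-field holding voltage across graded depolarizations.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so measurements are phase-true.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .inputs import LfpReference, circular_distance, circular_signed_distance

__all__ = [
    "FeatureSet",
    "ramp_extract",
    "theta_envelope",
    "theta_peak_phases",
    "phase_out_of_field",
    "precession_extent",
    "ramp_vs_holding_slope",
    "measure_condition",
    "extract_features",
    "circular_mean_deg",
]


# ---------------------------------------------------------------------------
# filters and small utilities
# ---------------------------------------------------------------------------

def _decim(batch) -> int:
    return max(1, int(getattr(batch.cfg, "feature_decimation", 1)))


def _fs_hz(batch) -> float:
    return 1000.0 / (batch.cfg.dt * _decim(batch))


def _dec_series(batch, arr) -> np.ndarray:
    """Down-sampled view used for all measurements.

    Membrane voltage is smooth on the 0.5 ms integration grid (τ_min = 5 ms)
    and every measured quantity lives below 10 Hz, so analysis runs at
    dt·decimation (2 ms by default) with no anti-alias filtering needed.
    """
    return np.asarray(arr)[_decim(batch) - 1::_decim(batch)]


@lru_cache(maxsize=32)
def lowpass_sos(cutoff_hz: float, fs_hz: float, order: int = 4):
    return butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")


@lru_cache(maxsize=32)
def bandpass_sos(low_hz: float, high_hz: float, fs_hz: float, order: int = 4):
    return butter(order, (low_hz, high_hz), btype="band", fs=fs_hz, output="sos")


def _bandpassed(batch) -> list[np.ndarray]:
    """Theta-band filtered, down-sampled single-trial traces."""
    cfg = batch.cfg
    sos = bandpass_sos(cfg.band_low_hz, cfg.band_high_hz, _fs_hz(batch))
    return [sosfiltfilt(sos, _dec_series(batch, v)) for v in batch.vs]


def circular_mean_deg(phases_deg) -> float:
    """Circular mean in degrees, in [0, 360)."""
    phases = np.deg2rad(np.asarray(phases_deg, dtype=float))
    if phases.size == 0:
        return float("nan")
    mean = np.angle(np.mean(np.exp(1j * phases)))
    out = float(np.rad2deg(mean) % 360.0)
    return 0.0 if out >= 360.0 else out


def circular_diff_deg(a, b) -> float:
    """Signed circular difference a − b wrapped to (−180, 180]."""
    d = (float(a) - float(b) + 180.0) % 360.0 - 180.0
    return d if d != -180.0 else 180.0


def _crossing_times(batch, center_pos: float) -> list[float]:
    """Times (ms) of post-warm-up crossings of a track position whose 0.4 s
    window fits inside the simulated trace (including its run-out tail)."""
    cfg = batch.cfg
    half_ms = cfg.window_s * 1000.0 / 2.0
    lap_ms = cfg.lap_duration_s * 1000.0
    t_end = float(batch.t_ms[-1])
    t0_ms = (center_pos % cfg.track_length) / cfg.speed * 1000.0
    out = []
    lap = 0
    while True:
        t_c = t0_ms + lap * lap_ms
        lap += 1
        if t_c > t_end:
            break
        if t_c - half_ms < lap_ms:        # still in (or touching) warm-up
            continue
        if t_c + half_ms <= t_end:
            out.append(t_c)
    if not out:
        raise ValueError("no complete measurement window inside the trace")
    return out


def _window_mean(batch, series_dec: np.ndarray, center_pos: float) -> float:
    """Mean of a (decimated) series over the 0.4 s windows at a position."""
    t_dec = _dec_series(batch, batch.t_ms)
    half_ms = batch.cfg.window_s * 1000.0 / 2.0
    vals = []
    for t_c in _crossing_times(batch, center_pos):
        sel = (t_dec > t_c - half_ms) & (t_dec <= t_c + half_ms)
        vals.append(series_dec[sel].mean())
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# core measurements
# ---------------------------------------------------------------------------

def ramp_extract(batch) -> dict:
    """Out-of-field Vm, in-field Vm and ramp amplitude (in − out), in mV."""
    cfg = batch.cfg
    v_mean = _dec_series(batch, np.mean(batch.vs, axis=0))
    low = sosfiltfilt(lowpass_sos(cfg.lowpass_hz, _fs_hz(batch)), v_mean)
    out_center = (batch.field_center + cfg.track_length / 2.0) % cfg.track_length
    vm_in = _window_mean(batch, low, batch.field_center)
    vm_out = _window_mean(batch, low, out_center)
    return {"vm_in": vm_in, "vm_out": vm_out, "ramp": vm_in - vm_out}


def theta_envelope(batch, bandpassed=None) -> dict:
    """In/out-of-field theta envelope amplitude (mV) via the analytic signal."""
    cfg = batch.cfg
    bandpassed = _bandpassed(batch) if bandpassed is None else bandpassed
    env = np.mean([np.abs(hilbert(bp)) for bp in bandpassed], axis=0)
    out_center = (batch.field_center + cfg.track_length / 2.0) % cfg.track_length
    return {"theta_in": _window_mean(batch, env, batch.field_center),
            "theta_out": _window_mean(batch, env, out_center)}


def theta_peak_phases(batch, bandpassed=None) -> tuple[np.ndarray, np.ndarray]:
    """LFP phases (deg) and positions (cm) of theta-band Vm peaks, all trials.

    Peaks are local maxima of the band-passed single-trial traces separated
    by at least half a theta period; only peaks inside the analysis laps are
    kept.
    """
    cfg = batch.cfg
    bandpassed = _bandpassed(batch) if bandpassed is None else bandpassed
    dt_dec = cfg.dt * _decim(batch)
    min_dist = max(1, int(round(0.5 / cfg.f_lfp * 1000.0 / dt_dec)))
    t_dec = _dec_series(batch, batch.t_ms)
    x_dec = _dec_series(batch, batch.x)
    lap_ms = cfg.lap_duration_s * 1000.0
    in_analysis = (t_dec > lap_ms) & (t_dec <= cfg.n_laps * lap_ms)
    phases, positions = [], []
    for bp, off in zip(bandpassed, batch.phi_offsets):
        idx, _ = find_peaks(bp, distance=min_dist)
        idx = idx[in_analysis[idx]]
        lfp = LfpReference(cfg.f_lfp, off)
        phases.append(lfp.phase(t_dec[idx]))
        positions.append(x_dec[idx])
    return np.concatenate(phases), np.concatenate(positions)


def phase_out_of_field(batch, peaks=None) -> float:
    """Circular-mean LFP phase (deg) of Vm theta peaks outside the field.

    "Outside" means circular distance from the field center greater than
    ``cfg.out_field_distance`` (beyond any ramp influence).
    """
    cfg = batch.cfg
    phases, positions = theta_peak_phases(batch) if peaks is None else peaks
    d = circular_distance(positions, batch.field_center, cfg.track_length)
    return circular_mean_deg(phases[d > cfg.out_field_distance])


def precession_extent(phases_deg, positions, field_center, cfg) -> float:
    """Extent (deg) of phase precession across the field-centered window.

    Peaks within ±(precession window/2 · running speed) of the field center
    are binned by signed circular distance (``cfg.position_bin`` cm bins);
    each bin's circular-mean phase is unwrapped greedily to the nearest
    cycle of its predecessor, and the extent is the unwrapped phase at
    window entry minus at window exit (positive = precession: phases get
    earlier as the animal advances).
    """
    half_cm = cfg.precession_window_s * cfg.speed / 2.0
    s = circular_signed_distance(positions, field_center, cfg.track_length)
    sel = np.abs(s) <= half_cm
    if not np.any(sel):
        return float("nan")
    edges = np.arange(-half_cm, half_cm + cfg.position_bin / 2.0, cfg.position_bin)
    idx = np.digitize(s[sel], edges) - 1
    ph = np.asarray(phases_deg)[sel]
    binned = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if np.any(in_bin):
            binned.append(circular_mean_deg(ph[in_bin]))
    if len(binned) < 2:
        return float("nan")
    unwrapped = [binned[0]]
    for p in binned[1:]:
        prev = unwrapped[-1]
        k = np.round((prev - p) / 360.0)
        unwrapped.append(p + 360.0 * k)
    return float(unwrapped[0] - unwrapped[-1])


def ramp_vs_holding_slope(points) -> float:
    """Least-squares slope (mV/mV) of ramp amplitude vs out-of-field Vm.

    ``points`` is a sequence of (vm_out, ramp_amplitude) pairs across graded
    depolarizations (the control condition included).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two (vm_out, ramp) points")
    return float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])


# ---------------------------------------------------------------------------
# condition- and protocol-level aggregation
# ---------------------------------------------------------------------------

def measure_condition(batch) -> dict:
    """All single-condition measurements from one SimBatch."""
    out = dict(ramp_extract(batch))
    bandpassed = _bandpassed(batch)
    out.update(theta_envelope(batch, bandpassed))
    peaks = theta_peak_phases(batch, bandpassed)
    out["phase_out"] = phase_out_of_field(batch, peaks)
    out["precession"] = precession_extent(peaks[0], peaks[1],
                                          batch.field_center, batch.cfg)
    out["dtheta_inout"] = out["theta_in"] - out["theta_out"]
    return out


@dataclass
class FeatureSet:
    """Scalar place-field features of one model (one network instance).

    Deltas are perturbed − control; ``dprecession_pct`` is the percent change
    of the precession extent under reduced inhibition.
    """

    vm_out: float = np.nan
    vm_in: float = np.nan
    ramp: float = np.nan
    theta_in: float = np.nan
    theta_out: float = np.nan
    dtheta_inout: float = np.nan
    phase_out_ctrl: float = np.nan
    phase_out_red: float = np.nan
    precession: float = np.nan
    precession_red: float = np.nan
    dvm_in: float = np.nan
    dvm_out: float = np.nan
    dtheta_in: float = np.nan
    dtheta_out: float = np.nan
    dprecession_pct: float = np.nan
    slope: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def mean(cls, sets: list["FeatureSet"]) -> "FeatureSet":
        """Across-instance average (circular mean for phase features)."""
        out = cls()
        for f in fields(cls):
            vals = [getattr(s, f.name) for s in sets]
            if f.name.startswith("phase_"):
                setattr(out, f.name, circular_mean_deg(vals))
            else:
                setattr(out, f.name, float(np.mean(vals)))
        return out


def extract_features(control, reduced=None, depol_batches=()) -> FeatureSet:
    """Assemble a FeatureSet from control / reduced-inhibition / depolarized
    batches of one network instance."""
    c = measure_condition(control)
    fs = FeatureSet(
        vm_out=c["vm_out"], vm_in=c["vm_in"], ramp=c["ramp"],
        theta_in=c["theta_in"], theta_out=c["theta_out"],
        dtheta_inout=c["dtheta_inout"], phase_out_ctrl=c["phase_out"],
        precession=c["precession"])
    if reduced is not None:
        r = measure_condition(reduced)
        fs.phase_out_red = r["phase_out"]
        fs.precession_red = r["precession"]
        fs.dvm_in = r["vm_in"] - c["vm_in"]
        fs.dvm_out = r["vm_out"] - c["vm_out"]
        fs.dtheta_in = r["theta_in"] - c["theta_in"]
        fs.dtheta_out = r["theta_out"] - c["theta_out"]
        if np.isfinite(c["precession"]) and c["precession"] != 0:
            fs.dprecession_pct = 100.0 * (r["precession"] - c["precession"]) / c["precession"]
    if depol_batches:
        pts = [(c["vm_out"], c["ramp"])]
        for b in depol_batches:
            m = ramp_extract(b)
            pts.append((m["vm_out"], m["ramp"]))
        fs.slope = ramp_vs_holding_slope(pts)
    return fs
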