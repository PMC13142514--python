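"""Synthetic presynaptic drive: spatial tuning, theta modulation, trajectory.

This module generates everything the model place cell "sees": a constant-speed
trajectory on a circular track, an LFP-like theta phase reference, a population
of CA3 place cells whose firing both encodes position (floor-Gaussian place
fields) and phase-precesses a full cycle through each field, and two
subpopulations of interneurons (positively and negatively spatially tuned)
that fire at a fixed preferred theta phase.

Two evaluation paths are provided:

* a direct per-neuron reference path (:func:`ca3_rate_matrix`,
  :func:`interneuron_rate_matrix`, :func:`population_rates`) that literally
  multiplies spatial tuning by temporal modulation for every neuron — clear,
  slow, and used as the oracle in tests;
* a fast path (:class:`Ca3DriveBasis`) that expands the circular exponential
  exp(k·cos θ) in modified Bessel functions so that weighted population sums
  of theta-modulated CA3 rates can be reassembled for any global phase offset
  and modulation depth from a handful of precomputed harmonic time series.
  This is what makes population-level parameter search affordable; the two
  paths are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import iv as bessel_iv

from .params import StudyConfig

__all__ = [
    "circular_signed_distance",
    "circular_distance",
    "floor_gaussian",
    "Trajectory",
    "LfpReference",
    "Ca3Population",
    "InterneuronPopulation",
    "calibrate_interneuron_rates",
    "inh_temporal_modulation",
    "ca3_target_phase",
    "ca3_temporal_modulation",
    "ca3_rate_matrix",
    "interneuron_rate_matrix",
    "population_rates",
    "Ca3DriveBasis",
]


# ---------------------------------------------------------------------------
# geometry and spatial tuning primitives
# ---------------------------------------------------------------------------

def circular_signed_distance(x, center, track_length):
    """Signed distance from ``center`` to ``x`` along a circular track, in
    (-track_length/2, track_length/2]. Positive values lie ahead of the
    center in the running direction."""
    d = (np.asarray(x, dtype=float) - center + track_length / 2.0) % track_length
    return d - track_length / 2.0


def circular_distance(x, center, track_length):
    return np.abs(circular_signed_distance(x, center, track_length))


def floor_gaussian(x, center, floor_width, track_length):
    """Gaussian-shaped spatial tuning clipped to exactly zero at the floor.

    A Gaussian of circular distance is shifted and rescaled so that the value
    is 1 at the center and exactly 0 at circular distance >= floor_width/2.
    The Gaussian sigma is floor_width/(3*sqrt(2)), which puts the floor at
    2.25 sigma-equivalents and keeps the profile visibly Gaussian inside the
    field while giving a hard out-of-field cutoff.
    """
    if floor_width > track_length:
        raise ValueError("floor_width cannot exceed track_length")
    d = circular_distance(x, center, track_length)
    sigma = floor_width / (3.0 * np.sqrt(2.0))
    c = np.exp(-((floor_width / 2.0) ** 2) / (2.0 * sigma**2))
    out = (np.exp(-(d**2) / (2.0 * sigma**2)) - c) / (1.0 - c)
    return np.clip(out, 0.0, None)


def floor_gaussian_track_mean(floor_width, track_length, n_quad=20001):
    """Track-average of the floor-Gaussian profile (direct quadrature)."""
    x = np.linspace(0.0, track_length, n_quad)
    y = floor_gaussian(x, track_length / 2.0, floor_width, track_length)
    return float(np.trapezoid(y, x) / track_length)


# ---------------------------------------------------------------------------
# trajectory and LFP reference
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Constant-speed run on a circular track, sampled at ``dt`` ms."""

    track_length: float
    speed: float          # cm/s
    dt: float             # ms
    n_steps: int

    @cached_property
    def t_ms(self) -> np.ndarray:
        return np.arange(1, self.n_steps + 1) * self.dt

    @cached_property
    def x(self) -> np.ndarray:
        return (self.speed * self.t_ms / 1000.0) % self.track_length

    @classmethod
    def from_config(cls, cfg: StudyConfig) -> "Trajectory":
        return cls(cfg.track_length, cfg.speed, cfg.dt, cfg.n_steps)


@dataclass
class LfpReference:
    """Global theta phase clock, analogous to an extracellular LFP.

    Phase is in degrees, advancing at 360*f_lfp deg/s; ``phi_offset`` is drawn
    uniformly per trial to decouple theta phase from spatial position.
    """

    f_lfp: float
    phi_offset: float = 0.0

    def phase(self, t_ms) -> np.ndarray:
        return (360.0 * self.f_lfp * np.asarray(t_ms) / 1000.0 + self.phi_offset) % 360.0


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class Ca3Population:
    """CA3 place-cell inputs: floor-Gaussian fields, full-cycle precession."""

    n: int
    track_length: float
    floor_width: float = 60.0
    r_max: float = 25.0
    d: float = 0.7
    k: float = 0.7
    phi_ca3: float = 180.0   # LFP phase crossed at the field center
    centers: np.ndarray = field(init=False)

    def __post_init__(self):
        self.centers = np.arange(self.n) * self.track_length / self.n

    def spatial_rate(self, x) -> np.ndarray:
        """Rates (Hz) of all cells at position(s) x; shape (..., n)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = circular_distance(x[..., None], self.centers, self.track_length)
        return self.r_max * floor_gaussian_from_distance(d, self.floor_width)

    @classmethod
    def from_config(cls, cfg: StudyConfig, phi_ca3: float = 180.0) -> "Ca3Population":
        return cls(cfg.n_ca3, cfg.track_length, cfg.ca3_floor_width,
                   cfg.ca3_peak_rate, cfg.d_ca3, cfg.k_ca3, phi_ca3)


def floor_gaussian_from_distance(d, floor_width):
    sigma = floor_width / (3.0 * np.sqrt(2.0))
    c = np.exp(-((floor_width / 2.0) ** 2) / (2.0 * sigma**2))
    return np.clip((np.exp(-(np.asarray(d) ** 2) / (2.0 * sigma**2)) - c) / (1.0 - c), 0.0, None)


@dataclass
class InterneuronPopulation:
    """One interneuron subpopulation with floor-Gaussian spatial modulation.

    ``polarity`` is "positive" (rate peaks at the modulation center) or
    "negative" (rate dips, reaching exactly 0 Hz at the trough). ``baseline``
    is the out-of-field rate and ``extremum`` the rate at the modulation
    center; both come from :func:`calibrate_interneuron_rates`.
    """

    polarity: str
    n: int
    track_length: float
    floor_width: float = 60.0
    baseline: float = 25.0
    extremum: float = 25.0
    d: float = 0.5
    phi_inh: float = 180.0
    centers: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        self.centers = np.arange(self.n) * self.track_length / self.n

    def spatial_rate(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = circular_distance(x[..., None], self.centers, self.track_length)
        shape = floor_gaussian_from_distance(d, self.floor_width)
        return self.baseline + (self.extremum - self.baseline) * shape

    @classmethod
    def calibrated(cls, polarity: str, cfg: StudyConfig, phi_inh: float = 180.0
                   ) -> "InterneuronPopulation":
        baseline, extremum = calibrate_interneuron_rates(
            polarity, cfg.inh_floor_width, cfg.track_length, cfg.inh_mean_rate,
            peak_to_baseline=cfg.pos_peak_to_baseline)
        return cls(polarity, cfg.n_inh_per_pop, cfg.track_length, cfg.inh_floor_width,
                   baseline, extremum, cfg.d_inh, phi_inh)


def calibrate_interneuron_rates(polarity, floor_width, track_length,
                                mean_rate=25.0, peak_to_baseline=None):
    """Solve for (baseline, extremum) so the spatial mean rate hits the target.

    The spatial profile is baseline + (extremum - baseline)·fg(x) where fg is
    the floor-Gaussian shape with track mean m. Negative polarity is
    constrained to reach exactly 0 Hz at the trough, which fixes both numbers:
    mean = b·(1 - m). The positive polarity is under-determined by the mean
    alone, so the peak-to-baseline ratio is a configuration input; with ratio
    r, mean = b·(1 + (r-1)·m).

    Returns (baseline, extremum); raises on infeasible combinations.
    """
    m = floor_gaussian_track_mean(floor_width, track_length)
    if polarity == "negative":
        if m >= 1.0:
            raise ValueError("shape mean >= 1: cannot reach the mean with a 0 Hz trough")
        baseline = mean_rate / (1.0 - m)
        return baseline, 0.0
    if polarity == "positive":
        r = 47.7 / 21.3 if peak_to_baseline is None else float(peak_to_baseline)
        if r <= 1.0:
            raise ValueError("positive polarity needs peak_to_baseline > 1")
        baseline = mean_rate / (1.0 + (r - 1.0) * m)
        return baseline, r * baseline
    raise ValueError(f"unknown polarity {polarity!r}")


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

def inh_temporal_modulation(t_ms, phi_offset, phi_inh, d_inh, f_lfp):
    """Interneuron theta modulation factor, in [1 - d_inh, 1].

    M(t) = d·(cos(2π·f·t + φ_offset − φ_inh) + 1)/2 + 1 − d, so the factor is
    maximal when the LFP phase equals the preferred phase φ_inh. Phases in
    degrees, t in ms.
    """
    theta = np.deg2rad(360.0 * f_lfp * np.asarray(t_ms, dtype=float) / 1000.0
                       + phi_offset - phi_inh)
    return d_inh * (np.cos(theta) + 1.0) / 2.0 + 1.0 - d_inh


def ca3_target_phase(x, center, floor_width, phi_ca3, track_length):
    """Target firing phase (deg) of a precessing CA3 cell at position x.

    Linear in the traversed fraction of the field: the phase starts
    phi_ca3+180° at field entry, crosses phi_ca3 at the center, and ends
    phi_ca3−180° at field exit — a full 360° of precession (phase moves
    *earlier* as the animal advances).
    """
    s = circular_signed_distance(x, center, track_length)
    return phi_ca3 - 360.0 * s / floor_width


def ca3_temporal_modulation(t_ms, x, center, lfp: LfpReference, *,
                            floor_width=60.0, phi_ca3=180.0, d=0.7, k=0.7,
                            track_length=200.0):
    """CA3 theta/phase-precession modulation factor, in [1 - d, 1].

    M̂ = exp(k·cos(φ_target(x) − φ_LFP(t))) is normalized to M̃ ∈ [0, 1] and
    mixed with depth d: M = d·M̃ + 1 − d.
    """
    target = ca3_target_phase(x, center, floor_width, phi_ca3, track_length)
    delta = np.deg2rad(target - lfp.phase(t_ms))
    m_hat = np.exp(k * np.cos(delta))
    m_tilde = (m_hat - np.exp(-k)) / (np.exp(k) - np.exp(-k))
    return d * m_tilde + 1.0 - d


# ---------------------------------------------------------------------------
# reference rate matrices (slow, per-neuron; the oracle path)
# ---------------------------------------------------------------------------

def ca3_rate_matrix(traj: Trajectory, lfp: LfpReference, pop: Ca3Population) -> np.ndarray:
    """Time-varying rates r_i(t) of every CA3 cell; shape (n_steps, n).

    Direct product of spatial tuning and temporal modulation. Memory scales
    as n_steps × n; intended for tests and small illustrative runs.
    """
    t = traj.t_ms
    x = traj.x
    spatial = pop.spatial_rate(x)
    mod = ca3_temporal_modulation(
        t[:, None], x[:, None], pop.centers[None, :], lfp,
        floor_width=pop.floor_width, phi_ca3=pop.phi_ca3, d=pop.d, k=pop.k,
        track_length=pop.track_length)
    return spatial * mod


def interneuron_rate_matrix(traj: Trajectory, lfp: LfpReference,
                            pop: InterneuronPopulation) -> np.ndarray:
    """Time-varying rates of every interneuron; shape (n_steps, n)."""
    spatial = pop.spatial_rate(traj.x)
    mod = inh_temporal_modulation(traj.t_ms, lfp.phi_offset, pop.phi_inh, pop.d, lfp.f_lfp)
    return spatial * mod[:, None]


def population_rates(traj: Trajectory, lfp: LfpReference, ca3: Ca3Population,
                     inh_pops: list[InterneuronPopulation]) -> dict:
    """All presynaptic rates for one trial (reference path)."""
    out = {"ca3": ca3_rate_matrix(traj, lfp, ca3)}
    for pop in inh_pops:
        out[pop.polarity] = interneuron_rate_matrix(traj, lfp, pop)
    return out


# ---------------------------------------------------------------------------
# fast weighted-sum drive basis
# ---------------------------------------------------------------------------

class Ca3DriveBasis:
    """Harmonic basis for weighted sums of theta-modulated CA3 rates.

    For a weight vector w over CA3 cells, the summed drive is

        S_w(t; φ, d) = Σ_i w_i R_i(x(t)) · [d·M̃_i(t; φ) + 1 − d]

    where M̃ is the normalized exp(k·cos Δ_i) factor and Δ_i(t) = α_i(t) + φ,
    with α_i(t) = φ_target,i(x(t))|_{φ_ca3=0} − 360·f·t and φ a global phase
    that absorbs both the cell population's preferred phase φ_ca3 and the
    per-trial LFP offset (φ = φ_ca3 − φ_offset). Expanding
    exp(k·cos θ) = Σ_m ε_m I_m(k) cos(mθ) turns S_w into a short linear
    combination of the complex harmonic series

        B_{w,m}(t) = Σ_i w_i R_i(x(t)) e^{i·m·α_i(t)},

    which are precomputed once per (trajectory, population, weight vector)
    and reused for every candidate parameter set and trial.
    """

    M_MAX = 6

    def __init__(self, traj: Trajectory, pop: Ca3Population, f_lfp: float,
                 weight_vectors: dict[str, np.ndarray], chunk: int = 1000):
        self.pop = pop
        self.k = pop.k
        self.f_lfp = float(f_lfp)
        self._iv = bessel_iv(np.arange(self.M_MAX + 1), pop.k)
        n_t = traj.n_steps
        names = list(weight_vectors)
        W = np.column_stack([np.asarray(weight_vectors[nm], dtype=float) for nm in names])
        basis = {nm: np.zeros((self.M_MAX + 1, n_t), dtype=complex) for nm in names}
        t = traj.t_ms
        x = traj.x
        for lo in range(0, n_t, chunk):
            hi = min(lo + chunk, n_t)
            s = circular_signed_distance(x[lo:hi, None], pop.centers[None, :],
                                         pop.track_length)
            r = pop.r_max * floor_gaussian_from_distance(np.abs(s), pop.floor_width)
            # α_i(t) with φ_ca3 = 0, in radians
            alpha = np.deg2rad(-360.0 * s / pop.floor_width
                               - 360.0 * self.f_lfp * t[lo:hi, None] / 1000.0)
            e1 = np.exp(1j * alpha)
            em = np.ones_like(e1)
            for m in range(self.M_MAX + 1):
                wr = r * em  # (chunk, n)
                for j, nm in enumerate(names):
                    basis[nm][m, lo:hi] = wr @ W[:, j]
                em = em * e1
        # store as contiguous (M+1, n_t) stacks so one complex matvec
        # reconstructs the drive for any global phase
        self._basis = {nm: np.ascontiguousarray(b) for nm, b in basis.items()}

    def summed_drive(self, name: str, phi_deg: float, d: float) -> np.ndarray:
        """S_w(t) in Hz for weight vector ``name`` at global phase φ (deg)."""
        B = self._basis[name]
        phi = np.deg2rad(phi_deg)
        k = self.k
        m_idx = np.arange(self.M_MAX + 1)
        coeffs = self._iv * np.exp(1j * m_idx * phi)
        coeffs[1:] *= 2.0
        q = (coeffs @ B).real
        p = B[0].real
        m_tilde_sum = (q - np.exp(-k) * p) / (np.exp(k) - np.exp(-k))
        return (1.0 - d) * p + d * m_tilde_sum
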