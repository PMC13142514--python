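"""Synaptic weights and probabilistic interneuron connectivity.

AMPAR weights from CA3 are a deterministic floor-Gaussian function of the
distance between each presynaptic field center and the CA1 cell's field
center (minimum 1, maximum 1+ΔW). NMDAR weights are all 1 (or all 0 for
models without NMDARs) and GABAR weights are all 1; what varies between the
uniform / balanced / reciprocal configurations is *which* interneurons are
connected. Connection probabilities are shaped by a floor-Gaussian
preference over interneuron modulation centers whose width equals the full
track length, so "near" preference falls smoothly to zero at the point
diametrically opposite the place field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .inputs import InterneuronPopulation, floor_gaussian

SCHEMES = ("uniform", "balanced", "reciprocal")


def ampar_weight_profile(ca3_centers, field_center, delta_w, floor_width=60.0,
                         track_length=200.0) -> np.ndarray:
    """Per-CA3-cell AMPAR weight: 1 + ΔW·fg(distance to the CA1 field)."""
    if delta_w < 0:
        raise ValueError("delta_w must be non-negative")
    return 1.0 + delta_w * floor_gaussian(ca3_centers, field_center,
                                          floor_width, track_length)


@dataclass
class Connectome:
    """One realization of the synaptic wiring onto the CA1 cell."""

    scheme: str
    seed: int
    w_ampar: np.ndarray          # per CA3 cell, in [1, 1+ΔW]
    w_nmdar: np.ndarray          # per CA3 cell, all 1 or all 0
    pos_mask: np.ndarray         # bool per positively tuned interneuron
    neg_mask: np.ndarray         # bool per negatively tuned interneuron

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": int(self.seed),
            "w_ampar": self.w_ampar.tolist(),
            "w_nmdar": self.w_nmdar.tolist(),
            "pos_mask": self.pos_mask.astype(int).tolist(),
            "neg_mask": self.neg_mask.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Connectome":
        d = json.loads(Path(path).read_text())
        return cls(d["scheme"], d["seed"],
                   np.asarray(d["w_ampar"], dtype=float),
                   np.asarray(d["w_nmdar"], dtype=float),
                   np.asarray(d["pos_mask"], dtype=bool),
                   np.asarray(d["neg_mask"], dtype=bool))


def connection_preference(scheme: str, polarity: str, centers, field_center,
                          pref_floor_width, track_length) -> np.ndarray:
    """Un-normalized connection preference over interneuron centers.

    uniform: flat. balanced: positively tuned interneurons are preferred
    near the field, negatively tuned ones far from it. reciprocal: the
    opposite. "Far" preference is the same floor-Gaussian centered on the
    point diametrically opposite the place field.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    centers = np.asarray(centers, dtype=float)
    if scheme == "uniform":
        return np.ones_like(centers)
    near = floor_gaussian(centers, field_center, pref_floor_width, track_length)
    far = floor_gaussian(centers, (field_center + track_length / 2.0) % track_length,
                         pref_floor_width, track_length)
    if scheme == "balanced":
        return near if polarity == "positive" else far
    return far if polarity == "positive" else near  # reciprocal


def calibrate_subpopulation_counts(pops: list[InterneuronPopulation], scheme: str,
                                   field_center: float, n_total: int,
                                   pref_floor_width: float = 200.0,
                                   n_quad: int = 2001) -> list[int]:
    """Split the connection budget so subpopulation drives are balanced.

    The expected summed conductance from a subpopulation is proportional to
    (number of connections) × (preference-weighted mean firing rate of its
    neurons), so counts are set inversely proportional to that mean rate and
    scaled to sum to ``n_total``. With both populations calibrated to the
    same 25 Hz spatial mean this reduces to an even split, but the general
    rule handles asymmetric populations too.
    """
    track_length = pops[0].track_length
    x = np.linspace(0.0, track_length, n_quad)
    mean_rates = []
    for pop in pops:
        pref = connection_preference(scheme, pop.polarity, pop.centers,
                                     field_center, pref_floor_width, track_length)
        per_cell = pop.spatial_rate(x).mean(axis=0)  # track-mean rate per neuron
        w = pref / pref.sum()
        mean_rates.append(float(per_cell @ w))
    inv = 1.0 / np.asarray(mean_rates)
    counts = inv / inv.sum() * n_total
    out = [int(round(c)) for c in counts]
    out[-1] = n_total - sum(out[:-1])
    return out


def connection_probabilities(scheme: str, pop: InterneuronPopulation,
                             field_center: float, n_connections: int,
                             pref_floor_width: float = 200.0) -> np.ndarray:
    """Per-neuron Bernoulli connection probability with expected count fixed."""
    if n_connections <= 0:
        raise ValueError("n_connections per subpopulation must be positive")
    if n_connections > pop.n:
        raise ValueError("requested more connections than interneurons")
    pref = connection_preference(scheme, pop.polarity, pop.centers, field_center,
                                 pref_floor_width, pop.track_length)
    p = n_connections * pref / pref.sum()
    if p.max() > 1.0:
        raise ValueError(
            "connection probability exceeds 1; reduce n_connections or flatten "
            "the preference")
    return p


def sample_inhibitory_connections(scheme: str, pops: list[InterneuronPopulation],
                                  field_center: float, n_connections: int,
                                  seed: int, ca3_centers=None, delta_w: float = 0.0,
                                  ampar_floor_width: float = 60.0,
                                  pref_floor_width: float = 200.0,
                                  nmdar_enabled: bool = True) -> Connectome:
    """Draw one connectome realization.

    Each interneuron connects independently (Bernoulli) with probability
    proportional to the scheme's preference, rescaled so the expected count
    per subpopulation matches the calibrated split of ``n_connections``.
    The uniform draws are fixed per seed, so increasing ``n_connections``
    grows the connectome monotonically.
    """
    counts = calibrate_subpopulation_counts(pops, scheme, field_center,
                                            n_connections, pref_floor_width)
    rng = np.random.default_rng(seed)
    masks = {}
    for pop, cnt in zip(pops, counts):
        p = connection_probabilities(scheme, pop, field_center, cnt, pref_floor_width)
        masks[pop.polarity] = rng.uniform(size=pop.n) < p
    track_length = pops[0].track_length
    if ca3_centers is None:
        w_ampar = np.array([])
        w_nmdar = np.array([])
    else:
        w_ampar = ampar_weight_profile(ca3_centers, field_center, delta_w,
                                       ampar_floor_width, track_length)
        w_nmdar = np.ones(len(ca3_centers)) if nmdar_enabled else np.zeros(len(ca3_centers))
    return Connectome(scheme, seed, w_ampar, w_nmdar,
                      masks["positive"], masks["negative"])


def expected_inhibitory_profile(scheme: str, pops: list[InterneuronPopulation],
                                field_center: float, n_connections: int, x,
                                pref_floor_width: float = 200.0) -> np.ndarray:
    """Analytic expectation of the summed connected spatial rate at x.

    E[A(x)] = Σ_j p_j ρ_j(x) over both subpopulations — the sampling-free
    oracle for the Monte-Carlo connectivity tests.
    """
    counts = calibrate_subpopulation_counts(pops, scheme, field_center,
                                            n_connections, pref_floor_width)
    total = np.zeros(len(np.atleast_1d(x)))
    for pop, cnt in zip(pops, counts):
        p = connection_probabilities(scheme, pop, field_center, cnt, pref_floor_width)
        total = total + pop.spatial_rate(x) @ p
    return total


def summed_inhibitory_rate(connectome: Connectome,
                           pops: list[InterneuronPopulation], x) -> np.ndarray:
    """Summed spatial rate A(x) of the connected interneurons (Hz)."""
    total = np.zeros(len(np.atleast_1d(x)))
    for pop in pops:
        mask = connectome.pos_mask if pop.polarity == "positive" else connectome.neg_mask
        if mask.any():
            total = total + pop.spatial_rate(x)[:, mask].sum(axis=1)
    return total
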