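"""Shared fixtures: a reduced-scale study configuration and simulation
contexts that keep the suite fast while preserving the full geometry of the
task (200 cm circular track, 7 Hz theta, 60 cm floor-width tuning)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ca1ei.params import StudyConfig
from ca1ei.runner import CandidateParams, SimContext, Variant

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def test_cfg() -> StudyConfig:
    """Down-scaled populations, full track/theta geometry."""
    return StudyConfig(n_ca3=200, n_inh_per_pop=100, n_inh_connections=60,
                       n_trials=2, n_instances=2)


@pytest.fixture(scope="session")
def uniform_ctx(test_cfg) -> SimContext:
    return SimContext(test_cfg, Variant("uniform", True), seed=7)


@pytest.fixture(scope="session")
def default_candidate() -> CandidateParams:
    return CandidateParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
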