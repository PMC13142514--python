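"""Synthetic input populations: spatial tuning, rate calibration, theta
modulation, phase precession, and the fast drive basis against the direct
per-neuron reference."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1ei.inputs import (Ca3DriveBasis, Ca3Population, InterneuronPopulation,
                          LfpReference, Trajectory, ca3_rate_matrix,
                          ca3_target_phase, ca3_temporal_modulation,
                          calibrate_interneuron_rates, circular_signed_distance,
                          floor_gaussian, floor_gaussian_track_mean,
                          inh_temporal_modulation, interneuron_rate_matrix,
                          population_rates)
from ca1ei.params import StudyConfig

L = 200.0


# ---------------------------------------------------------------------------
# floor-Gaussian spatial tuning
# ---------------------------------------------------------------------------

class TestFloorGaussian:
    def test_unity_at_center(self):
        assert floor_gaussian(50.0, 50.0, 60.0, L) == pytest.approx(1.0)

    def test_zero_at_and_beyond_floor(self):
        assert floor_gaussian(80.0, 50.0, 60.0, L) == pytest.approx(0.0, abs=1e-12)
        assert floor_gaussian(150.0, 50.0, 60.0, L) == 0.0

    def test_wraps_around_the_track(self):
        # positions 5 and 195 are 10 cm apart on the circle
        assert floor_gaussian(195.0, 5.0, 60.0, L) == pytest.approx(
            floor_gaussian(15.0, 5.0, 60.0, L))

    @given(st.floats(0, 30), st.floats(0, L))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_about_center(self, delta, center):
        a = floor_gaussian(center + delta, center, 60.0, L)
        b = floor_gaussian(center - delta, center, 60.0, L)
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_decrease_with_distance(self):
        d = np.linspace(0, 30, 100)
        vals = floor_gaussian(50.0 + d, 50.0, 60.0, L)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_floor_wider_than_track_rejected(self):
        with pytest.raises(ValueError):
            floor_gaussian(0.0, 0.0, 250.0, L)


# ---------------------------------------------------------------------------
# CA3 spatial rates
# ---------------------------------------------------------------------------

class TestCa3Spatial:
    def test_peak_rate_at_center(self):
        pop = Ca3Population(10, L)
        rates = pop.spatial_rate(pop.centers[3])
        assert rates[0, 3] == pytest.approx(25.0)

    def test_zero_out_of_field(self):
        pop = Ca3Population(10, L)
        x = (pop.centers[0] + 30.0) % L
        assert pop.spatial_rate(x)[0, 0] == 0.0

    def test_track_average_below_peak(self):
        pop = Ca3Population(4, L)
        x = np.linspace(0, L, 4001)
        assert pop.spatial_rate(x)[:, 0].mean() < 25.0

    def test_summed_population_rate_translation_invariant(self):
        # equally spaced fields: the summed rate is flat around the circle
        pop = Ca3Population(200, L)
        x = np.linspace(0, L, 1001)
        total = pop.spatial_rate(x).sum(axis=1)
        assert total.std() / total.mean() < 0.01


# ---------------------------------------------------------------------------
# interneuron rate calibration
# ---------------------------------------------------------------------------

class TestInterneuronCalibration:
    def test_negative_polarity_baseline(self):
        # 0 Hz trough + mean 25 Hz fixes the out-of-field baseline near 29 Hz
        baseline, trough = calibrate_interneuron_rates("negative", 60.0, L, 25.0)
        assert trough == 0.0
        m = floor_gaussian_track_mean(60.0, L)
        assert baseline == pytest.approx(25.0 / (1.0 - m))
        assert baseline == pytest.approx(29.2, rel=0.02)

    def test_nearly_flat_shape_gives_mean_baseline(self):
        baseline, peak = calibrate_interneuron_rates("positive", 60.0, L, 25.0,
                                                     peak_to_baseline=1.0001)
        assert baseline == pytest.approx(25.0, abs=0.01)

    @pytest.mark.parametrize("polarity", ["positive", "negative"])
    def test_track_mean_hits_target_by_quadrature(self, polarity):
        cfg = StudyConfig(n_inh_per_pop=50)
        pop = InterneuronPopulation.calibrated(polarity, cfg)
        x = np.linspace(0, L, 20001)
        mean = pop.spatial_rate(x)[:, 0].mean()
        assert mean == pytest.approx(25.0, abs=0.01)

    def test_calibration_idempotent(self):
        a = calibrate_interneuron_rates("negative", 60.0, L, 25.0)
        b = calibrate_interneuron_rates("negative", 60.0, L, 25.0)
        assert a == b

    def test_negative_rates_never_below_zero(self):
        cfg = StudyConfig(n_inh_per_pop=20)
        pop = InterneuronPopulation.calibrated("negative", cfg)
        x = np.linspace(0, L, 5001)
        assert pop.spatial_rate(x).min() >= 0.0

    def test_infeasible_ratio_rejected(self):
        with pytest.raises(ValueError):
            calibrate_interneuron_rates("positive", 60.0, L, 25.0,
                                        peak_to_baseline=0.9)


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

class TestInhTemporalModulation:
    def test_range_and_extremes(self):
        t = np.linspace(0, 1000.0 / 7.0, 5000)  # one theta cycle
        m = inh_temporal_modulation(t, 0.0, 0.0, 0.5, 7.0)
        assert m.max() == pytest.approx(1.0, abs=1e-6)
        assert m.min() == pytest.approx(0.5, abs=1e-6)

    def test_maximum_at_preferred_phase(self):
        phi_inh = 123.0
        t = np.linspace(0, 1000.0 / 7.0, 20000)
        m = inh_temporal_modulation(t, 0.0, phi_inh, 0.5, 7.0)
        lfp = LfpReference(7.0, 0.0)
        assert lfp.phase(t[np.argmax(m)]) == pytest.approx(phi_inh, abs=0.5)

    def test_cycle_average(self):
        t = np.linspace(0, 1000.0 / 7.0, 100001)[:-1]
        m = inh_temporal_modulation(t, 40.0, 10.0, 0.5, 7.0)
        assert m.mean() == pytest.approx(1.0 - 0.5 / 2.0, abs=1e-4)


class TestCa3TargetPhase:
    def test_center_crossing(self):
        assert ca3_target_phase(50.0, 50.0, 60.0, 180.0, L) == pytest.approx(180.0)

    def test_full_cycle_across_field(self):
        entry = ca3_target_phase(20.0, 50.0, 60.0, 180.0, L)
        exit_ = ca3_target_phase(80.0, 50.0, 60.0, 180.0, L)
        assert entry - exit_ == pytest.approx(360.0)

    @given(st.floats(0, 30))
    @settings(deadline=None, max_examples=30)
    def test_midpoint_symmetry(self, delta):
        lo = ca3_target_phase(50.0 - delta, 50.0, 60.0, 180.0, L)
        hi = ca3_target_phase(50.0 + delta, 50.0, 60.0, 180.0, L)
        # circular comparison: lo + hi ≡ 2·phi_ca3 = 360 ≡ 0 (mod 360)
        total = lo + hi - 2 * 180.0
        assert abs(total - 360.0 * round(total / 360.0)) < 1e-9

    def test_phase_decreases_with_position(self):
        x = np.linspace(25.0, 75.0, 50)
        phases = ca3_target_phase(x, 50.0, 60.0, 180.0, L)
        assert np.all(np.diff(phases) < 0)


class TestCa3TemporalModulation:
    def test_unity_when_target_matches_lfp(self):
        lfp = LfpReference(7.0, 0.0)
        t = 500.0
        phase_now = lfp.phase(t)
        # place the cell so its target phase at x equals the LFP phase
        x = 50.0
        phi_ca3 = (phase_now + 360.0 * circular_signed_distance(x, 50.0, L) / 60.0) % 360.0
        m = ca3_temporal_modulation(t, x, 50.0, lfp, phi_ca3=phi_ca3)
        assert m == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_floor(self):
        lfp = LfpReference(7.0, 0.0)
        t = 500.0
        phi_ca3 = (lfp.phase(t) + 180.0) % 360.0
        m = ca3_temporal_modulation(t, 50.0, 50.0, lfp, phi_ca3=phi_ca3, d=0.7)
        assert m == pytest.approx(0.3, abs=1e-9)

    def test_range(self):
        lfp = LfpReference(7.0, 77.0)
        t = np.linspace(0, 2000, 20000)
        m = ca3_temporal_modulation(t, 50.0, 50.0, lfp, phi_ca3=180.0, d=0.7)
        assert m.min() >= 0.3 - 1e-9 and m.max() <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# full rate matrices and the drive basis
# ---------------------------------------------------------------------------

def _small_setup(phi_offset=33.0, phi_ca3=200.0):
    cfg = StudyConfig(n_ca3=40, n_laps=2, tail_pad_s=0.0, dt=2.0)
    traj = Trajectory.from_config(cfg)
    pop = Ca3Population(cfg.n_ca3, L, phi_ca3=phi_ca3)
    lfp = LfpReference(cfg.f_lfp, phi_offset)
    return cfg, traj, pop, lfp


class TestPopulationRates:
    def test_rates_nonnegative_and_peak_bounded(self):
        cfg, traj, pop, lfp = _small_setup()
        rates = ca3_rate_matrix(traj, lfp, pop)
        assert rates.min() >= 0.0
        assert rates.max() <= 25.0 + 1e-9

    def test_peak_rate_reached_at_center_and_preferred_phase(self):
        # a cell crossing its center exactly at its target phase fires at 25 Hz
        cfg, traj, pop, lfp = _small_setup()
        rates = ca3_rate_matrix(traj, lfp, pop)
        cell = 7
        idx = np.argmin(np.abs(circular_signed_distance(traj.x, pop.centers[cell], L)))
        m = ca3_temporal_modulation(traj.t_ms[idx], traj.x[idx], pop.centers[cell],
                                    lfp, phi_ca3=pop.phi_ca3)
        assert rates[idx, cell] == pytest.approx(25.0 * m, rel=1e-9)

    def test_interneuron_rates_bounded_by_modulation_range(self):
        cfg = StudyConfig(n_inh_per_pop=30, n_laps=2, tail_pad_s=0.0, dt=2.0)
        traj = Trajectory.from_config(cfg)
        pop = InterneuronPopulation.calibrated("positive", cfg)
        lfp = LfpReference(cfg.f_lfp, 10.0)
        rates = interneuron_rate_matrix(traj, lfp, pop)
        assert rates.min() >= 0.5 * pop.baseline - 1e-9
        assert rates.max() <= pop.extremum + 1e-9

    def test_population_rates_bundle(self):
        cfg, traj, pop, lfp = _small_setup()
        inh = [InterneuronPopulation.calibrated(p, StudyConfig(n_inh_per_pop=10))
               for p in ("positive", "negative")]
        out = population_rates(traj, lfp, pop, inh)
        assert set(out) == {"ca3", "positive", "negative"}
        assert all(v.min() >= 0.0 for v in out.values())


class TestDriveBasis:
    def test_matches_reference_weighted_sums(self):
        """The Bessel-harmonic fast path reproduces the direct per-neuron
        weighted rate sums for arbitrary phases and weights."""
        cfg, traj, pop, lfp = _small_setup(phi_offset=123.0, phi_ca3=0.0)
        w_field = floor_gaussian(pop.centers, 100.0, 60.0, L)
        basis = Ca3DriveBasis(traj, pop, cfg.f_lfp,
                              {"base": np.ones(cfg.n_ca3), "field": w_field})
        for phi_ca3 in (0.0, 180.0, 247.0):
            pop_ref = Ca3Population(cfg.n_ca3, L, phi_ca3=phi_ca3)
            rates = ca3_rate_matrix(traj, lfp, pop_ref)
            for name, w in (("base", np.ones(cfg.n_ca3)), ("field", w_field)):
                ref = rates @ w
                fast = basis.summed_drive(name, phi_ca3 - lfp.phi_offset, cfg.d_ca3)
                assert np.abs(fast - ref).max() < 1e-6 * ref.max()

    def test_modulation_depth_is_linear_knob(self):
        cfg, traj, pop, lfp = _small_setup(phi_ca3=0.0)
        basis = Ca3DriveBasis(traj, pop, cfg.f_lfp, {"base": np.ones(cfg.n_ca3)})
        s0 = basis.summed_drive("base", 50.0, 0.0)
        s1 = basis.summed_drive("base", 50.0, 1.0)
        s_mid = basis.summed_drive("base", 50.0, 0.4)
        assert np.allclose(s_mid, 0.6 * s0 + 0.4 * s1, atol=1e-9)
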