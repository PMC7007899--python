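"""Closed-loop simulator vs its analytic frequency-response oracle."""

import numpy as np
import pytest

from posturolab import (
    BalanceModelParams,
    LearningCohortConfig,
    SimulatedFallError,
    UnstableLoopError,
    analytic_frf,
    build_prts,
    estimate_coherence,
    estimate_frf,
    segment_cycles,
    simulate_learning_cohort,
    simulate_sway,
)
from posturolab.simulate import DEFAULT_GEOMETRY, _check_stable


class TestAnalyticFRF:
    def test_low_frequency_gain_approaches_w_prop(self, quiet_params):
        """Integral control drives the DC stimulus gain to the
        proprioceptive weight."""
        H = analytic_frf(quiet_params, np.array([1e-5]))
        assert abs(H[0]) == pytest.approx(quiet_params.w_prop, rel=1e-3)

    def test_zero_weight_zero_response(self):
        p = BalanceModelParams(w_prop=0.0)
        H = analytic_frf(p, np.array([0.05, 0.5, 2.0]))
        assert np.allclose(np.abs(H), 0.0)

    def test_resonance_exceeds_high_frequency_gain(self, quiet_params):
        grid = np.linspace(0.02, 3.0, 400)
        H = np.abs(analytic_frf(quiet_params, grid))
        peak_f = grid[np.argmax(H)]
        assert H.max() > np.abs(analytic_frf(quiet_params, np.array([3.0])))[0]
        # gain peak lies in the 0.1-0.3 Hz band typical of tilt posturography
        assert 0.1 <= peak_f <= 0.3

    def test_unstable_loop_rejected(self):
        # negligible damping with a long delay destabilizes the loop
        with pytest.raises(UnstableLoopError, match="unstable"):
            analytic_frf(
                BalanceModelParams(Kd=0.0, delay=0.4), np.array([0.1])
            )

    def test_negative_frequency_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            analytic_frf(quiet_params, np.array([0.0, 0.1]))


class TestSimulateSway:
    def test_rest_stays_at_rest(self, design, quiet_params):
        stim = build_prts(design, 0.0, 1)
        rec = simulate_sway(stim, quiet_params, seed=0)
        assert np.allclose(rec.com_angle, 0.0, atol=1e-12)

    def test_deterministic_given_seed(self, pp4_stimulus):
        p = BalanceModelParams(noise_sd=1.5, cop_noise_sd=1e-3)
        a = simulate_sway(pp4_stimulus, p, seed=7)
        b = simulate_sway(pp4_stimulus, p, seed=7)
        assert np.array_equal(a.com_angle, b.com_angle)
        assert np.array_equal(a.cop_x, b.cop_x)

    def test_frf_matches_analytic_oracle(self, pp4_stimulus, pp4_recording, quiet_params):
        """Noise-free loop reproduces the closed-form response within
        2% gain / 2 deg phase at every excited harmonic."""
        cs = segment_cycles(pp4_recording, 20.0, discard_first=True)
        fr = estimate_frf(cs, pp4_stimulus.excited_frequencies)
        H = analytic_frf(quiet_params, pp4_stimulus.excited_frequencies)
        assert np.all(np.abs(fr.gain / np.abs(H) - 1) < 0.02)
        phase_th = np.degrees(np.unwrap(np.angle(H)))
        assert np.all(np.abs(fr.phase - phase_th) < 2.0)

    def test_noise_free_coherence_is_one(self, pp4_stimulus, pp4_recording):
        cs = segment_cycles(pp4_recording, 20.0, discard_first=True)
        coh = estimate_coherence(cs, pp4_stimulus.excited_frequencies)
        assert np.all(np.abs(coh - 1.0) < 0.01)

    def test_coherence_decreases_with_noise(self, pp4_stimulus):
        cohs = []
        for sd in (0.5, 4.0):
            rec = simulate_sway(
                pp4_stimulus, BalanceModelParams(noise_sd=sd), seed=5
            )
            cs = segment_cycles(rec, 20.0, discard_first=True)
            cohs.append(
                estimate_coherence(cs, pp4_stimulus.excited_frequencies).mean()
            )
        assert 1.0 > cohs[0] > cohs[1]

    def test_superposition_in_linear_regime(self, design, quiet_params):
        """Response to (A + B) equals the sum of the responses, noise-free."""
        a = build_prts(design, 0.44, 2)
        b = build_prts(design, 0.89, 2)
        both = build_prts(design, 0.44 + 0.89, 2)
        ra = simulate_sway(a, quiet_params, seed=0).com_angle
        rb = simulate_sway(b, quiet_params, seed=0).com_angle
        rab = simulate_sway(both, quiet_params, seed=0).com_angle
        assert np.allclose(rab, ra + rb, atol=1e-9)

    def test_simulated_gain_bounded_by_analytic_peak(self, pp4_stimulus, pp4_recording, quiet_params):
        cs = segment_cycles(pp4_recording, 20.0, discard_first=True)
        fr = estimate_frf(cs, pp4_stimulus.excited_frequencies)
        grid = np.linspace(0.02, 3.0, 500)
        peak = np.abs(analytic_frf(quiet_params, grid)).max()
        assert fr.gain.max() <= peak * 1.05

    def test_divergence_raises_simulated_fall(self, pp4_stimulus):
        p = BalanceModelParams(Kp=660.0, Kd=5.0, Ki=0.0, delay=0.3)
        with pytest.raises((SimulatedFallError, UnstableLoopError), match="fall|unstable"):
            _check_stable(p)
            simulate_sway(pp4_stimulus, p, seed=0)

    def test_cop_tracks_com_in_quasi_static_motion(self, design, quiet_params):
        """Slow stimulus: COP stays close to the COM projection."""
        slow = build_prts(design, 0.1, 2)
        rec = simulate_sway(slow, quiet_params, seed=0)
        com_proj = quiet_params.com_height * np.sin(np.deg2rad(rec.com_angle))
        # dynamic term J theta'' / (m g) is second order for slow sway
        assert np.max(np.abs(rec.cop_x - com_proj)) < 0.004


class TestLearningCohort:
    def test_cohort_size(self, learning_stimulus):
        cfg = LearningCohortConfig(n_subjects=1, n_trials=2, seed=0)
        recs = simulate_learning_cohort(cfg, learning_stimulus)
        assert len(recs) == 2
        assert {r.subject_id for r in recs} == {"S00"}

    def test_setpoint_drift_reaches_configured_end(self, learning_stimulus):
        """Mean lean across the cohort moves from ~3.3 toward ~2.4 deg."""
        cfg = LearningCohortConfig(
            n_subjects=6, n_trials=40, seed=2, noise_sd=0.5, drift_tau_trials=10.0
        )
        recs = simulate_learning_cohort(cfg, learning_stimulus)
        first = np.mean([r.com_angle.mean() for r in recs if r.trial_label == "learn000"])
        last = np.mean([r.com_angle.mean() for r in recs if r.trial_label == "learn039"])
        assert first > last
        assert first == pytest.approx(3.3, abs=0.6)
        assert last == pytest.approx(2.4, abs=0.6)

    def test_drift_disabled_trials_statistically_identical(self, learning_stimulus):
        cfg = LearningCohortConfig(
            n_subjects=1, n_trials=2, seed=4, drift_enabled=False, noise_sd=0.0
        )
        recs = simulate_learning_cohort(cfg, learning_stimulus)
        assert np.allclose(recs[0].com_angle, recs[1].com_angle, atol=1e-12)


def test_geometry_com_height_consistency():
    g = DEFAULT_GEOMETRY
    assert g.com_height == pytest.approx(0.56 * g.body_height, rel=1e-3)
    ch, cs = g.truth_coefficients
    assert ch > 0 and cs > 0
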