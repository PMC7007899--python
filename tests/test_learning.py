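"""Per-trial learning-sequence metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturolab import (
    LearningCohortConfig,
    amplitude_spectrum,
    compute_trial_metrics,
    detrend_trial,
    feedback_score,
    metrics_table,
    partition_psd,
    simulate_learning_cohort,
    stim_gain_phase,
)

FS = 100.0
T = np.arange(800) / FS


class TestDetrend:
    def test_pure_line_recovered(self):
        intercept, slope, resid = detrend_trial(3.3 - 0.05 * T, FS)
        assert intercept == pytest.approx(3.3, abs=1e-12)
        assert slope == pytest.approx(-0.05, abs=1e-12)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_midpoint_even_sine_has_zero_slope(self):
        # a sinusoid even about the sample-grid midpoint is orthogonal to the
        # linear regressor, so the fitted slope vanishes
        tm = (T[0] + T[-1]) / 2
        _, slope, _ = detrend_trial(np.cos(2 * np.pi * 1.0 * (T - tm)), FS)
        assert abs(slope) < 1e-9

    def test_line_plus_sine_slope_recovered(self):
        tm = (T[0] + T[-1]) / 2
        y = 1.2 + 0.07 * T + 0.5 * np.cos(2 * np.pi * 0.5 * (T - tm))
        _, slope, _ = detrend_trial(y, FS)
        assert slope == pytest.approx(0.07, abs=1e-9)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            detrend_trial(np.zeros(700), FS)


class TestAmplitudeSpectrum:
    def test_sine_amplitude_scaling(self):
        """2|X_k|/N recovers the time-domain sine amplitude."""
        amps = amplitude_spectrum(0.5 * np.sin(2 * np.pi * 1.0 * T), FS)
        assert amps[7] == pytest.approx(0.5, abs=1e-12)  # bin 8 = 1.0 Hz
        others = np.delete(amps, 7)
        assert np.all(others < 1e-12)

    def test_constant_trace_is_silent(self):
        assert np.all(amplitude_spectrum(np.full(800, 2.0), FS) < 1e-12)

    def test_two_sines_exactly_separated(self):
        y = 0.3 * np.sin(2 * np.pi * 1.0 * T) + 0.8 * np.sin(2 * np.pi * 1.25 * T)
        amps = amplitude_spectrum(y, FS)
        assert amps[7] == pytest.approx(0.3, abs=1e-12)
        assert amps[9] == pytest.approx(0.8, abs=1e-12)


class TestPartition:
    def test_energy_only_at_stimulus_bin(self):
        spec = np.zeros(16)
        spec[7] = 1.3  # 1.0 Hz
        full, stim, low, high = partition_psd(spec)
        assert stim == full and low == 0 and high == 0

    def test_energy_only_at_low_bin(self):
        spec = np.zeros(16)
        spec[1] = 0.7  # 0.25 Hz
        full, stim, low, high = partition_psd(spec)
        assert low == full and stim == 0 and high == 0

    def test_flat_spectrum_counts_2_2_12(self):
        full, stim, low, high = partition_psd(np.full(16, 0.5))
        assert (stim, low, high) == pytest.approx(
            (2 * 0.25, 2 * 0.25, 12 * 0.25)
        )
        assert full == pytest.approx(stim + low + high)


class TestFeedbackScore:
    def test_single_sine_fb_50(self):
        spec = amplitude_spectrum(0.5 * np.sin(2 * np.pi * 1.0 * T), FS)
        fb, dominant = feedback_score(spec, 0.0)
        assert fb == pytest.approx(50.0, abs=1e-9)
        assert dominant == "sway"

    def test_pure_drift_fb_200(self):
        fb, dominant = feedback_score(np.zeros(16), 0.2)
        assert fb == pytest.approx(200.0)
        assert dominant == "drift"

    def test_75_percent_sway_is_dominant(self):
        """amplitudes summing 3 deg + 0.1 deg/s drift: 300/400 = 75% > 70%."""
        spec = np.zeros(16)
        spec[:6] = 0.5
        fb, dominant = feedback_score(spec, 0.1)
        assert fb == pytest.approx(400.0)
        assert dominant == "sway"

    def test_boundary_70_percent_not_dominant(self):
        spec = np.zeros(16)
        spec[0] = 0.7  # sway part 70, drift part 30: exactly 70% excluded
        fb, dominant = feedback_score(spec, 0.03)
        assert fb == pytest.approx(100.0)
        assert dominant is None


class TestStimGainPhase:
    def test_identity(self, learning_stimulus):
        g, p = stim_gain_phase(
            learning_stimulus.samples, learning_stimulus.samples, FS, detrend=False
        )
        assert g == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_scaled_delay(self, learning_stimulus):
        """com = 0.5 x stimulus delayed 100 ms: gain 0.5, phase the
        amplitude-weighted mean of -360 f dt."""
        stim = learning_stimulus.samples
        resp = 0.5 * np.roll(stim, 10)  # 100 ms at 100 Hz, periodic trace
        g, p = stim_gain_phase(resp, stim, FS, detrend=False)
        assert g == pytest.approx(0.5, abs=1e-12)
        w = np.array([2.2282973143, 1.7826378515])  # |a1|, |a2|
        expected = np.sum(w * (-360.0 * np.array([1.0, 1.25]) * 0.1)) / w.sum()
        assert p == pytest.approx(expected, abs=1e-6)

    def test_detrended_pipeline_close_to_exact(self, learning_stimulus):
        stim = learning_stimulus.samples
        resp = 0.5 * np.roll(stim, 10)
        g, p = stim_gain_phase(resp, stim, FS, detrend=True)
        assert g == pytest.approx(0.5, rel=0.02)

    def test_zero_stimulus_rejected(self):
        with pytest.raises(ValueError, match="zero amplitude"):
            stim_gain_phase(np.zeros(800), np.zeros(800), FS)

    def test_simulated_trial_matches_analytic_oracle(
        self, learning_stimulus, quiet_params
    ):
        from posturolab import analytic_frf, simulate_sway

        rec = simulate_sway(learning_stimulus, quiet_params, seed=0)
        g, p = stim_gain_phase(rec.com_angle, learning_stimulus.samples, FS)
        H = analytic_frf(quiet_params, np.array([1.0, 1.25]))
        w = np.abs(np.fft.rfft(learning_stimulus.samples)[[8, 10]])
        g_th = np.sum(w * np.abs(H)) / w.sum()
        ang = np.degrees(np.unwrap(np.angle(H)))
        if ang[0] > 180:
            ang -= 360
        p_th = np.sum(w * ang) / w.sum()
        assert g == pytest.approx(g_th, rel=0.02)
        assert p == pytest.approx(p_th, abs=2.0)


class TestPipeline:
    def test_psd_partition_is_exact(self, learning_stimulus, quiet_params):
        from posturolab import simulate_sway

        rec = simulate_sway(
            learning_stimulus,
            type(quiet_params)(noise_sd=1.5, lean_setpoint=3.0),
            seed=2,
        )
        m = compute_trial_metrics(rec.com_angle, learning_stimulus.samples, FS)
        assert m.full_psd == pytest.approx(m.stim_psd + m.low_psd + m.high_psd)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(c=st.floats(0.2, 5.0))
    def test_linear_scale_covariance(self, learning_stimulus, c):
        """Scaling the COM trace by c scales amplitudes by c, PSDs by c^2,
        the fb sway term by c, and leaves phase unchanged."""
        rng = np.random.default_rng(5)
        trace = (
            2.0
            + 0.4 * np.sin(2 * np.pi * 1.0 * T + 0.3)
            + 0.2 * np.sin(2 * np.pi * 0.25 * T + 1.0)
            + 0.05 * rng.standard_normal(800)
        )
        m1 = compute_trial_metrics(trace, learning_stimulus.samples, FS)
        m2 = compute_trial_metrics(c * trace, learning_stimulus.samples, FS)
        assert m2.full_psd == pytest.approx(c**2 * m1.full_psd, rel=1e-9)
        assert m2.stim_psd == pytest.approx(c**2 * m1.stim_psd, rel=1e-9)
        assert m2.gain_stim == pytest.approx(c * m1.gain_stim, rel=1e-9)
        assert m2.phase_stim == pytest.approx(m1.phase_stim, abs=1e-6)
        assert m2.drift_slope == pytest.approx(c * m1.drift_slope, rel=1e-9)

    def test_cohort_stim_psd_decays_with_configured_drift(self, learning_stimulus):
        """End-to-end: exponential decay of stimulus-evoked sway shows up as
        a falling stim_psd across trials."""
        cfg = LearningCohortConfig(
            n_subjects=4, n_trials=30, seed=7, noise_sd=1.0, drift_tau_trials=8.0
        )
        recs = simulate_learning_cohort(cfg, learning_stimulus)
        df = metrics_table(recs, learning_stimulus)
        by_trial = df.groupby("trial_index")["stim_psd"].mean()
        assert by_trial.iloc[:3].mean() > by_trial.iloc[-5:].mean()
        # configured PSD reduction is ~33%; at tau=8 trials the end of a
        # 30-trial run is essentially converged
        ratio = by_trial.iloc[-5:].mean() / by_trial.iloc[0]
        assert ratio == pytest.approx(0.67, abs=0.15)
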