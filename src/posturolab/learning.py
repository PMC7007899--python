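"""Per-trial analysis of the 8-s rhythmic learning sequences.

Each trial's COM trace is linearly detrended (the intercept at t = 0 is the
"starting position", the slope the drift), the residual is Fourier
transformed with amplitudes scaled to time-domain sine amplitudes
(2|X_k|/N) on the 0.125-Hz grid up to 2 Hz, and the 16-bin spectrum is
partitioned into stimulus bins (1.0 and 1.25 Hz), low-frequency bins
(0.125 and 0.250 Hz, which dominate the spontaneous sway) and the 12
remaining high-frequency bins.  PSD per group is the sum of squared
amplitudes.  The feedback score reported to subjects after each trial is

    fb = sum_k |y(k)| * 100 + |s| * 1000

over the 0.125-2 Hz amplitude bins, with the dominant component named when
it exceeds 70% of the score (strict inequality).  Gain and phase at the two
stimulus frequencies are combined by stimulus-amplitude weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SwayRecording
from .stimuli import StimulusSequence

__all__ = [
    "LearningTrialMetrics",
    "detrend_trial",
    "amplitude_spectrum",
    "partition_psd",
    "feedback_score",
    "stim_gain_phase",
    "compute_trial_metrics",
    "metrics_table",
    "FREQ_RESOLUTION",
    "N_BINS",
    "STIM_FREQS",
    "LOW_FREQS",
]

FREQ_RESOLUTION = 0.125  # Hz, 8-s window
N_BINS = 16  # bins 0.125 .. 2.0 Hz
STIM_FREQS = (1.0, 1.25)
LOW_FREQS = (0.125, 0.25)


@dataclass
class LearningTrialMetrics:
    """The nine per-trial scalars plus bookkeeping.

    PSDs in deg^2, drift in deg/s, starting position in deg, phase in
    degrees (lag negative).  ``full_psd == stim_psd + low_psd + high_psd``
    exactly by construction.
    """

    full_psd: float
    stim_psd: float
    low_psd: float
    high_psd: float
    drift_slope: float
    starting_position: float
    feedback: float
    gain_stim: float
    phase_stim: float
    subject_id: str = ""
    trial_index: int = 0
    dominant: str | None = None


def detrend_trial(
    com_trace: np.ndarray, sample_rate: float, duration: float = 8.0
) -> tuple[float, float, np.ndarray]:
    """Remove the least-squares line; returns (intercept, slope, residual).

    The intercept is reported at t = 0 (the starting position).
    """
    com_trace = np.asarray(com_trace, dtype=float)
    n_expected = duration * sample_rate
    if len(com_trace) != int(round(n_expected)):
        raise ValueError(
            f"trace length {len(com_trace)} != duration x sample_rate = "
            f"{n_expected:g}"
        )
    t = np.arange(len(com_trace)) / sample_rate
    slope, intercept = np.polyfit(t, com_trace, 1)
    residual = com_trace - (intercept + slope * t)
    return float(intercept), float(slope), residual


def amplitude_spectrum(residual: np.ndarray, sample_rate: float) -> np.ndarray:
    """Single-sided sine amplitudes (deg) at bins k x 0.125 Hz, k = 1..16."""
    residual = np.asarray(residual, dtype=float)
    n = len(residual)
    X = np.fft.rfft(residual)
    amps = 2.0 * np.abs(X) / n
    duration = n / sample_rate
    k = np.round(np.arange(1, N_BINS + 1) * FREQ_RESOLUTION * duration).astype(int)
    return amps[k]


def _bin_index(freq: float) -> int:
    return int(round(freq / FREQ_RESOLUTION)) - 1


def partition_psd(spectrum: np.ndarray) -> tuple[float, float, float, float]:
    """Partition the 16-bin spectrum into (full, stim, low, high) PSDs.

    PSD per group is the sum of squared amplitudes; the three groups
    partition the bins exactly so full = stim + low + high.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if len(spectrum) != N_BINS:
        raise ValueError(f"expected a {N_BINS}-bin spectrum")
    p = spectrum**2
    stim_idx = [_bin_index(f) for f in STIM_FREQS]
    low_idx = [_bin_index(f) for f in LOW_FREQS]
    stim = float(p[stim_idx].sum())
    low = float(p[low_idx].sum())
    full = float(p.sum())
    return full, stim, low, full - stim - low


def feedback_score(
    spectrum: np.ndarray, slope: float, dominance_threshold: float = 0.70
) -> tuple[float, str | None]:
    """Composite feedback score and its dominant component (if any).

    fb = sum|amplitudes| x 100 + |slope| x 1000.  A component is dominant
    only when it strictly exceeds ``dominance_threshold`` of the score.
    """
    sway_part = float(np.sum(np.abs(spectrum))) * 100.0
    drift_part = abs(float(slope)) * 1000.0
    fb = sway_part + drift_part
    dominant = None
    if fb > 0:
        if sway_part > dominance_threshold * fb:
            dominant = "sway"
        elif drift_part > dominance_threshold * fb:
            dominant = "drift"
    return fb, dominant


def stim_gain_phase(
    com_trace: np.ndarray,
    stimulus_trace: np.ndarray,
    sample_rate: float,
    detrend: bool = True,
) -> tuple[float, float]:
    """Stimulus-frequency gain and phase of one learning trial.

    Complex response/stimulus ratios at 1.0 and 1.25 Hz, combined by
    stimulus-amplitude-weighted averaging of moduli and (pairwise unwrapped)
    angles.  Raises if the stimulus carries no energy at either bin.
    """
    com_trace = np.asarray(com_trace, dtype=float)
    stimulus_trace = np.asarray(stimulus_trace, dtype=float)
    if len(com_trace) != len(stimulus_trace):
        raise ValueError("trace lengths differ")
    n = len(com_trace)
    duration = n / sample_rate
    if detrend:
        _, _, com_trace = detrend_trial(com_trace, sample_rate, duration)
    k = np.round(np.array(STIM_FREQS) * duration).astype(int)
    S = np.fft.rfft(stimulus_trace)[k]
    R = np.fft.rfft(com_trace)[k]
    w = np.abs(S)
    if np.any(w < 1e-12):
        raise ValueError("stimulus has zero amplitude at a stimulus frequency")
    H = R / S
    gain = float(np.sum(w * np.abs(H)) / np.sum(w))
    ang = np.degrees(np.unwrap(np.angle(H)))
    if ang[0] > 180.0:
        ang -= 360.0
    phase = float(np.sum(w * ang) / np.sum(w))
    return gain, phase


def compute_trial_metrics(
    com_trace: np.ndarray,
    stimulus_trace: np.ndarray,
    sample_rate: float,
    subject_id: str = "",
    trial_index: int = 0,
) -> LearningTrialMetrics:
    """Run the full per-trial pipeline on one 8-s trace pair."""
    intercept, slope, residual = detrend_trial(com_trace, sample_rate)
    spectrum = amplitude_spectrum(residual, sample_rate)
    full, stim, low, high = partition_psd(spectrum)
    fb, dominant = feedback_score(spectrum, slope)
    gain, phase = stim_gain_phase(residual, stimulus_trace, sample_rate, detrend=False)
    return LearningTrialMetrics(
        full_psd=full,
        stim_psd=stim,
        low_psd=low,
        high_psd=high,
        drift_slope=slope,
        starting_position=intercept,
        feedback=fb,
        gain_stim=gain,
        phase_stim=phase,
        subject_id=subject_id,
        trial_index=trial_index,
        dominant=dominant,
    )


METRIC_COLUMNS = [
    "full_psd",
    "stim_psd",
    "low_psd",
    "high_psd",
    "drift_slope",
    "starting_position",
    "feedback",
    "gain_stim",
    "phase_stim",
]


def metrics_table(
    recordings: list[SwayRecording],
    stimulus: StimulusSequence,
    response_fn=None,
) -> pd.DataFrame:
    """Per-trial metrics for a cohort: one row per (subject, trial).

    ``response_fn(rec) -> trace`` selects the COM trace (default: the
    recording's own COM channel, i.e. truth for simulated data or the
    calibrated channel if it was stored there).  Trial indices are 0-based,
    parsed from trailing digits of ``trial_label`` when present.
    """
    rows = []
    counters: dict[str, int] = {}
    for rec in recordings:
        trace = response_fn(rec) if response_fn is not None else rec.com_angle
        label_digits = "".join(c for c in rec.trial_label if c.isdigit())
        if label_digits:
            idx = int(label_digits)
        else:
            idx = counters.get(rec.subject_id, 0)
        counters[rec.subject_id] = idx + 1
        m = compute_trial_metrics(
            trace, stimulus.samples, rec.sample_rate, rec.subject_id, idx
        )
        rows.append(
            {
                "subject_id": m.subject_id,
                "trial_index": m.trial_index,
                **{c: getattr(m, c) for c in METRIC_COLUMNS},
                "dominant": m.dominant,
            }
        )
    return pd.DataFrame(rows).sort_values(["subject_id", "trial_index"]).reset_index(
        drop=True
    )
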