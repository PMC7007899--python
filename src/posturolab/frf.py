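"""Cycle-segmented frequency-response and coherence estimation.

Responses to the pseudo-random stimulus are cut into stimulus cycles
(discarding the first cycle of each trial to avoid onset transients), the
DFT is taken per cycle, and the complex body-sway / stimulus ratio is
averaged across cycles at the excited harmonics.  Gain is the magnitude of
the averaged ratio, phase its unwrapped angle in degrees (lag negative).
Magnitude-squared coherence uses cycle-averaged cross- and auto-spectra:

    coh(f) = |<S* R>|^2 / (<|S|^2> <|R|^2>)

which is 1 for a noise-free linear response and has expectation ~1/N for a
response independent of the stimulus averaged over N cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import SwayRecording

__all__ = [
    "CycleSet",
    "FrequencyResponse",
    "segment_cycles",
    "concat_cycle_sets",
    "estimate_frf",
    "estimate_coherence",
    "mean_sway_response",
    "band_average",
]


@dataclass
class CycleSet:
    """Per-cycle stimulus and response matrices (cycle x sample, degrees)."""

    stimulus_cycles: np.ndarray
    response_cycles: np.ndarray
    cycle_duration: float
    sample_rate: float
    provenance: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        s, r = np.atleast_2d(self.stimulus_cycles), np.atleast_2d(self.response_cycles)
        if s.shape != r.shape:
            raise ValueError("stimulus and response cycle matrices differ in shape")
        expected = int(round(self.cycle_duration * self.sample_rate))
        if s.shape[1] != expected:
            raise ValueError(
                f"cycle length {s.shape[1]} != cycle_duration x sample_rate = {expected}"
            )
        self.stimulus_cycles, self.response_cycles = s, r

    @property
    def n_cycles(self) -> int:
        return self.stimulus_cycles.shape[0]

    def take(self, idx: np.ndarray) -> "CycleSet":
        """Row-resampled copy (bootstrap helper)."""
        return CycleSet(
            self.stimulus_cycles[idx],
            self.response_cycles[idx],
            self.cycle_duration,
            self.sample_rate,
            [self.provenance[i] for i in idx] if self.provenance else [],
        )


@dataclass
class FrequencyResponse:
    """Per-frequency gain, phase (deg, lag negative) and coherence."""

    freqs: np.ndarray
    gain: np.ndarray
    phase: np.ndarray
    coherence: np.ndarray | None
    n_cycles: int
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.gain < 0):
            raise ValueError("gain must be >= 0")
        if self.coherence is not None and (
            np.any(self.coherence < -1e-12) or np.any(self.coherence > 1 + 1e-12)
        ):
            raise ValueError("coherence must lie in [0, 1]")


def segment_cycles(
    rec: SwayRecording,
    cycle_duration: float,
    discard_first: bool = True,
    response: np.ndarray | None = None,
) -> CycleSet:
    """Cut a recording into consecutive stimulus cycles.

    ``response`` defaults to the recording's (truth or calibrated) COM-angle
    channel.  The recording must span an integer number of cycles.
    """
    if response is None:
        if rec.com_angle is None:
            raise ValueError("recording has no COM channel; pass response=")
        response = rec.com_angle
    n_per = cycle_duration * rec.sample_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("cycle_duration x sample_rate must be an integer")
    n_per = int(round(n_per))
    n = len(rec.platform_tilt)
    n_cycles, rem = divmod(n, n_per)
    if rem:
        raise ValueError(
            f"recording duration {n / rec.sample_rate:g} s is not an integer "
            f"number of {cycle_duration:g}-s cycles "
            f"(residual {rem / rec.sample_rate:g} s)"
        )
    stim = rec.platform_tilt[: n_cycles * n_per].reshape(n_cycles, n_per)
    resp = np.asarray(response)[: n_cycles * n_per].reshape(n_cycles, n_per)
    start = 1 if discard_first else 0
    prov = [(rec.subject_id, rec.trial_label, c) for c in range(start, n_cycles)]
    return CycleSet(stim[start:], resp[start:], cycle_duration, rec.sample_rate, prov)


def concat_cycle_sets(sets: list[CycleSet]) -> CycleSet:
    """Pool cycles from several recordings (e.g. across subjects)."""
    first = sets[0]
    for cs in sets[1:]:
        if cs.cycle_duration != first.cycle_duration or cs.sample_rate != first.sample_rate:
            raise ValueError("cycle sets have inconsistent timing")
    return CycleSet(
        np.vstack([cs.stimulus_cycles for cs in sets]),
        np.vstack([cs.response_cycles for cs in sets]),
        first.cycle_duration,
        first.sample_rate,
        sum((cs.provenance for cs in sets), []),
    )


def _harmonic_bins(cs: CycleSet, excited: np.ndarray) -> np.ndarray:
    k = np.asarray(excited, dtype=float) * cs.cycle_duration
    if np.any(np.abs(k - np.round(k)) > 1e-6):
        raise ValueError("excited frequencies must be harmonics of 1/cycle_duration")
    return np.round(k).astype(int)


def estimate_frf(cs: CycleSet, excited: np.ndarray) -> FrequencyResponse:
    """Estimate the FRF by cycle-averaging per-cycle spectral ratios.

    Frequencies at which the stimulus carries (numerically) no energy are
    dropped with a warning.
    """
    if cs.n_cycles < 2:
        raise ValueError("need at least 2 cycles for an averaged FRF")
    k = _harmonic_bins(cs, excited)
    S = np.fft.rfft(cs.stimulus_cycles, axis=1)[:, k]
    R = np.fft.rfft(cs.response_cycles, axis=1)[:, k]
    stim_amp = np.abs(S).mean(axis=0)
    ok = stim_amp > 1e-12 * max(stim_amp.max(), 1e-30)
    if not np.all(ok):
        dropped = np.asarray(excited)[~ok]
        warnings.warn(
            f"dropping frequencies with zero stimulus amplitude: {dropped}",
            stacklevel=2,
        )
    S, R = S[:, ok], R[:, ok]
    H = (R / S).mean(axis=0)
    phase = np.degrees(np.unwrap(np.angle(H)))
    # anchor the unwrap so the lowest-frequency phase lies in (-180, 180]
    if phase[0] > 180.0:
        phase -= 360.0 * np.ceil((phase[0] - 180.0) / 360.0)
    elif phase[0] <= -180.0:
        phase += 360.0 * np.ceil((-180.0 - phase[0]) / 360.0 + 1e-12)
    return FrequencyResponse(
        freqs=np.asarray(excited, dtype=float)[ok],
        gain=np.abs(H),
        phase=phase,
        coherence=None,
        n_cycles=cs.n_cycles,
    )


def estimate_coherence(cs: CycleSet, excited: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence from cycle-averaged spectra.

    Refuses fewer than two cycles (single-cycle coherence is identically 1).
    """
    if cs.n_cycles < 2:
        raise ValueError(
            "coherence needs >= 2 cycles (a single cycle gives identically 1)"
        )
    k = _harmonic_bins(cs, excited)
    S = np.fft.rfft(cs.stimulus_cycles, axis=1)[:, k]
    R = np.fft.rfft(cs.response_cycles, axis=1)[:, k]
    cross = (np.conj(S) * R).mean(axis=0)
    denom = (np.abs(S) ** 2).mean(axis=0) * (np.abs(R) ** 2).mean(axis=0)
    return np.abs(cross) ** 2 / denom


def mean_sway_response(cs: CycleSet) -> np.ndarray:
    """Cycle-wise mean time-domain response (per-trial offset retained; the
    offset carries the mean body-lean information)."""
    return cs.response_cycles.mean(axis=0)


def band_average(fr: FrequencyResponse, n_bands: int = 11) -> FrequencyResponse:
    """Logarithmically band-averaged copy of a FRF for display.

    Raw per-harmonic values should be retained alongside; this is a
    presentation aid, not an estimator change.
    """
    edges = np.geomspace(fr.freqs.min(), fr.freqs.max() * (1 + 1e-9), n_bands + 1)
    idx = np.clip(np.searchsorted(edges, fr.freqs, side="right") - 1, 0, n_bands - 1)
    freqs, gain, phase, coh = [], [], [], []
    for b in range(n_bands):
        sel = idx == b
        if not np.any(sel):
            continue
        freqs.append(np.exp(np.mean(np.log(fr.freqs[sel]))))
        gain.append(fr.gain[sel].mean())
        phase.append(fr.phase[sel].mean())
        if fr.coherence is not None:
            coh.append(fr.coherence[sel].mean())
    return FrequencyResponse(
        freqs=np.array(freqs),
        gain=np.array(gain),
        phase=np.array(phase),
        coherence=np.array(coh) if fr.coherence is not None else None,
        n_cycles=fr.n_cycles,
    )
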