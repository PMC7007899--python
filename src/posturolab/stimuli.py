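"""Tilt-stimulus construction.

Two stimulus families are supported:

* Pseudo-random ternary sequences (PRTS): a maximal-length sequence over
  GF(3) mapped to velocity steps {-v, 0, +v} and integrated to a
  piecewise-linear platform tilt-angle trace.  One cycle is
  ``(3**m - 1) * step_duration`` seconds long; the default degree-4 design
  gives the classic 80-step, 20-s cycle whose nonzero velocities of
  0.44, 0.89 and 1.78 deg/s integrate to peak-to-peak tilt amplitudes of
  1, 2 and 4 degrees ("pp1", "pp2", "pp4").
* A short rhythmic "learning" stimulus: an 8-s superposition of a 1-Hz and
  a 1.25-Hz sine with a toes-down bias (extremes 5.3 deg toes-down,
  2.6 deg toes-up in the toes-up-positive convention used throughout).

Sign convention everywhere: toes-up tilt is positive, toes-down negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TernaryDesign",
    "StimulusSequence",
    "LearningStimulusParams",
    "NonPrimitiveTapsError",
    "generate_ternary_symbols",
    "build_prts",
    "build_learning_sequence",
    "solve_learning_params",
    "assemble_session",
    "PP_VELOCITIES",
    "DEFAULT_SAMPLE_RATE",
]

#: default recording/command rate in Hz; all PRTS step boundaries fall on
#: samples at this rate (0.25 s steps).
DEFAULT_SAMPLE_RATE = 100.0

#: nonzero velocity magnitudes (deg/s) paired with peak-to-peak tilt
#: amplitude labels. With the default design (excursion 9 steps x 0.25 s)
#: these integrate to 0.99, 2.0025 and 4.005 deg peak-to-peak.
PP_VELOCITIES = {"pp1": 0.44, "pp2": 0.89, "pp4": 1.78}


class NonPrimitiveTapsError(ValueError):
    """Raised when a ternary recurrence does not generate a maximal-length
    sequence (achieved period is reported in the message)."""


@dataclass(frozen=True)
class TernaryDesign:
    """Generator configuration for a pseudo-random ternary sequence.

    The symbol recurrence is ``a_n = sum_i taps[i] * a_{n-1-i}  (mod 3)``
    started from the register state ``(0, ..., 0, 1)``.  ``taps`` must define
    a primitive recurrence so the symbol period is ``3**register_order - 1``.

    The default ``taps=(1, 0, 0, 1)`` / ``symbol_map={0: 0, 1: 1, 2: -1}``
    was selected by enumerating all primitive degree-4 recurrences and both
    nonzero symbol mappings and keeping a configuration whose cumulative-sum
    excursion equals 9 steps, which reproduces the standard velocity ->
    peak-to-peak amplitude pairings (see :data:`PP_VELOCITIES`).
    """

    register_order: int = 4
    taps: tuple[int, ...] = (1, 0, 0, 1)
    symbol_map: tuple[int, int, int] = (0, 1, -1)  # images of field elements 0,1,2
    step_duration: float = 0.25

    def __post_init__(self) -> None:
        if self.register_order < 2:
            raise ValueError("register_order must be >= 2")
        if len(self.taps) != self.register_order:
            raise ValueError("taps length must equal register_order")
        if sorted(self.symbol_map) != [-1, 0, 1] or self.symbol_map[0] != 0:
            raise ValueError("symbol_map must map field 0 -> 0 and {1,2} -> {+1,-1}")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")

    @property
    def steps_per_cycle(self) -> int:
        return 3**self.register_order - 1

    @property
    def cycle_duration(self) -> float:
        return self.step_duration * self.steps_per_cycle


@dataclass
class StimulusSequence:
    """A platform tilt-angle trace with cycle structure.

    ``samples`` holds tilt angle in degrees (toes-up positive) at
    ``sample_rate`` Hz; the trace is ``n_cycles`` repetitions of a
    ``cycle_duration``-second cycle.  ``excited_frequencies`` lists the
    harmonics (Hz) at which the stimulus carries energy.
    """

    samples: np.ndarray
    sample_rate: float
    cycle_duration: float
    n_cycles: int
    excited_frequencies: np.ndarray
    label: str
    velocity_magnitude: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = self.sample_rate * self.cycle_duration * self.n_cycles
        if abs(len(self.samples) - expected) > 1:
            raise ValueError(
                f"trace length {len(self.samples)} does not match "
                f"sample_rate x cycle_duration x n_cycles = {expected:g}"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def generate_ternary_symbols(design: TernaryDesign) -> np.ndarray:
    """Return one period of the maximal-length ternary sequence mapped to
    {-1, 0, +1}.

    Raises
    ------
    NonPrimitiveTapsError
        If the recurrence is not primitive; the message reports the achieved
        period (or the degenerate absorption into the all-zero state).
    """
    m = design.register_order
    full_period = 3**m - 1
    state = (0,) * (m - 1) + (1,)
    seen = {state: 0}
    symbols: list[int] = []
    for n in range(3**m + 1):
        symbols.append(state[-1])
        nxt = sum(t * s for t, s in zip(design.taps, reversed(state))) % 3
        state = state[1:] + (nxt,)
        if all(s == 0 for s in state):
            raise NonPrimitiveTapsError(
                "degenerate register: taps drive the state into the all-zero "
                f"state after {n + 1} steps"
            )
        if state in seen:
            period = n + 1 - seen[state]
            if period == full_period:
                mapping = np.array(design.symbol_map)
                return mapping[np.array(symbols[:period])]
            raise NonPrimitiveTapsError(
                f"taps {design.taps} are not primitive: achieved period "
                f"{period} < 3^{m} - 1 = {full_period}"
            )
        seen[state] = n + 1
    raise NonPrimitiveTapsError(  # unreachable: state space is finite
        f"taps {design.taps} are not primitive over GF(3)"
    )


def _position_trace(
    symbols: np.ndarray,
    velocity_magnitude: float,
    design: TernaryDesign,
    n_cycles: int,
    sample_rate: float,
) -> np.ndarray:
    """Integrate the velocity staircase to a tilt-angle trace starting at 0."""
    spp = design.step_duration * sample_rate
    if abs(spp - round(spp)) > 1e-9:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is not an integer multiple of "
            f"1/step_duration = {1 / design.step_duration:g} Hz; step "
            "boundaries must fall on samples"
        )
    spp = int(round(spp))
    vel = np.repeat(symbols * velocity_magnitude, spp)  # deg/s, one cycle
    vel = np.tile(vel, n_cycles)
    # position at sample n is the integral of the staircase up to t_n
    pos = np.concatenate([[0.0], np.cumsum(vel[:-1]) / sample_rate])
    return pos


def _excited_harmonics(
    cycle: np.ndarray, sample_rate: float, cycle_duration: float, threshold: float
) -> np.ndarray:
    """Harmonics k/cycle_duration whose single-sided amplitude is at least
    ``threshold`` times the maximal harmonic amplitude."""
    n = len(cycle)
    amps = np.abs(np.fft.rfft(cycle)) * 2.0 / n
    amps[0] = 0.0  # DC is not a stimulus harmonic
    freqs = np.arange(len(amps)) / cycle_duration
    keep = amps >= threshold * amps.max()
    keep[0] = False
    return freqs[keep]


def build_prts(
    design: TernaryDesign,
    velocity_magnitude: float,
    n_cycles: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    excited_threshold: float = 0.1,
    label: str | None = None,
) -> StimulusSequence:
    """Build a PRTS tilt-angle stimulus.

    The symbol sequence is scaled to a +/-``velocity_magnitude`` deg/s
    staircase and cumulatively integrated to a position trace starting at
    0 deg.  Because +1 and -1 symbols balance over a period, every cycle
    starts at exactly 0 deg.
    """
    if velocity_magnitude < 0:
        raise ValueError("velocity_magnitude must be >= 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    symbols = generate_ternary_symbols(design)
    pos = _position_trace(symbols, velocity_magnitude, design, n_cycles, sample_rate)
    n_cycle_samples = int(round(design.cycle_duration * sample_rate))
    excited = _excited_harmonics(
        pos[:n_cycle_samples], sample_rate, design.cycle_duration, excited_threshold
    )
    if label is None:
        pp = np.ptp(pos[:n_cycle_samples]) if velocity_magnitude > 0 else 0.0
        label = f"pp{pp:.0f}" if pp > 0 else "prts"
    return StimulusSequence(
        samples=pos,
        sample_rate=sample_rate,
        cycle_duration=design.cycle_duration,
        n_cycles=n_cycles,
        excited_frequencies=excited,
        label=label,
        velocity_magnitude=velocity_magnitude,
    )


@dataclass(frozen=True)
class LearningStimulusParams:
    """Parameters of the 8-s rhythmic learning stimulus.

    trace(t) = offset + a1 sin(2 pi f1 t + phase1) + a2 sin(2 pi f2 t + phase2)

    Defaults are the solved calibrated values (see
    :func:`solve_learning_params`): phases fixed at 0, a2 = -(f1/f2) a1 so the
    platform starts at rest, and (a1, offset) chosen so the trace extremes are
    5.3 deg toes-down and 2.6 deg toes-up.
    """

    f1: float = 1.0
    f2: float = 1.25
    a1: float = 2.2282973143
    a2: float = -1.7826378515
    phase1: float = 0.0
    phase2: float = 0.0
    offset: float = -1.35
    duration: float = 8.0

    def __post_init__(self) -> None:
        for f in (self.f1, self.f2):
            cycles = f * self.duration
            if abs(cycles - round(cycles)) > 1e-9:
                raise ValueError(
                    f"frequency {f} Hz does not complete an integer number of "
                    f"cycles in {self.duration} s"
                )


def solve_learning_params(
    min_tilt: float = -5.3,
    max_tilt: float = 2.6,
    f1: float = 1.0,
    f2: float = 1.25,
    duration: float = 8.0,
) -> LearningStimulusParams:
    """Solve the under-determined learning-stimulus parameters.

    Fixes phase1 = phase2 = 0, imposes a zero-velocity start
    (f1 a1 + f2 a2 = 0) and solves (a1, offset) so the trace extremes equal
    ``min_tilt`` and ``max_tilt``.  Deterministic: extremes of the unit shape
    are located on a dense grid and polished with a bounded scalar optimizer.
    """
    tgrid = np.arange(0.0, duration, duration / 200_000)

    def shape(t):
        return np.sin(2 * np.pi * f1 * t) - (f1 / f2) * np.sin(2 * np.pi * f2 * t)

    h = shape(tgrid)

    def refine(idx: int, sign: float) -> float:
        lo = tgrid[max(idx - 1, 0)]
        hi = tgrid[min(idx + 1, len(tgrid) - 1)]
        res = minimize_scalar(
            lambda t: -sign * shape(np.array([t]))[0], bounds=(lo, hi), method="bounded"
        )
        return sign * -res.fun

    hmax = refine(int(np.argmax(h)), +1.0)
    hmin = refine(int(np.argmin(h)), -1.0)
    a1 = (max_tilt - min_tilt) / (hmax - hmin)
    offset = max_tilt - a1 * hmax
    return LearningStimulusParams(
        f1=f1, f2=f2, a1=a1, a2=-(f1 / f2) * a1, offset=offset, duration=duration
    )


def build_learning_sequence(
    params: LearningStimulusParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> StimulusSequence:
    """Build the 8-s two-sine learning stimulus (one cycle)."""
    if params is None:
        params = LearningStimulusParams()
    n = params.duration * sample_rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration x sample_rate must be an integer")
    t = np.arange(int(round(n))) / sample_rate
    trace = (
        params.offset
        + params.a1 * np.sin(2 * np.pi * params.f1 * t + params.phase1)
        + params.a2 * np.sin(2 * np.pi * params.f2 * t + params.phase2)
    )
    return StimulusSequence(
        samples=trace,
        sample_rate=sample_rate,
        cycle_duration=params.duration,
        n_cycles=1,
        excited_frequencies=np.array([params.f1, params.f2]),
        label="learning",
    )


def assemble_session(
    design: TernaryDesign | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    n_cycles: int = 18,
    warmup_cycles: int = 2,
    seed: int | None = None,
) -> list[StimulusSequence]:
    """Assemble the PRTS block of a session.

    Returns a 120-s warm-up (``warmup_cycles`` cycles of each amplitude,
    ascending) followed by the three 18-cycle test sequences in a seeded
    random order of amplitudes.
    """
    if design is None:
        design = TernaryDesign()
    rng = np.random.default_rng(seed)
    labels = list(PP_VELOCITIES)
    warm_parts = [
        build_prts(design, PP_VELOCITIES[lab], warmup_cycles, sample_rate).samples
        for lab in labels
    ]
    warmup = StimulusSequence(
        samples=np.concatenate(warm_parts),
        sample_rate=sample_rate,
        cycle_duration=design.cycle_duration,
        n_cycles=warmup_cycles * len(labels),
        excited_frequencies=_excited_harmonics(
            warm_parts[-1][: int(round(design.cycle_duration * sample_rate))],
            sample_rate,
            design.cycle_duration,
            0.1,
        ),
        label="warmup",
    )
    order = rng.permutation(labels)
    tests = [
        build_prts(design, PP_VELOCITIES[lab], n_cycles, sample_rate, label=lab)
        for lab in order
    ]
    return [warmup] + tests


def design_as_dict(design: TernaryDesign) -> dict:
    """JSON-serializable form of a design (for sidecar/config files)."""
    return dataclasses.asdict(design)
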