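# posturolab

Analysis toolkit for support-surface-tilt posturography — the experiment
family in which a standing subject balances on a platform that rotates
about the ankle axis while body sway is recorded. It is aimed at balance
researchers who need the full chain from stimulus design to statistics in
one reproducible, testable package:

- **Stimulus design** — pseudo-random ternary sequences (PRTS: maximal-
  length GF(3) sequences mapped to velocity steps {−v, 0, +v} and
  integrated to tilt angle; the standard 80-step, 20-s cycle whose
  0.44/0.89/1.78 °/s velocities give 1/2/4° peak-to-peak amplitudes) and
  an 8-s rhythmic two-sine learning stimulus (1 + 1.25 Hz, toes-down
  biased, extremes −5.3°/+2.6°).
- **Closed-loop sway simulator** — an inverted pendulum stabilized by a
  delayed PID controller acting on a weighted mix of proprioceptive
  (body-to-platform) and graviceptive (body-in-space) error channels, with
  filtered torque noise, two-segment marker geometry and a torque-balance
  COP channel. Its closed-form frequency response
  `H(f) = w·PC/(1+PC)` is the exact oracle every estimator is tested
  against, and cohorts with configurable trial-to-trial parameter drift
  provide learning data with known ground truth.
- **COM calibration** — quasi-static COP regression on hip/shoulder
  markers, converting translations to angular center-of-mass sway.
- **FRF / coherence** — cycle-segmented frequency-response gain, phase and
  magnitude-squared coherence at the excited PRTS harmonics.
- **Bootstrap** — cycle-resampling confidence bounds (sorted-replicate
  index rule, e.g. the 10th/390th of 400 replicates for 95%).
- **Trend model** — Bayesian hierarchical regression
  `metric ~ seq + (seq | subject)` across 75 learning trials with
  Normal(0, 10) / Half-Cauchy(0, 2) priors, sampled by an ensemble MCMC on
  the analytically marginalized posterior, with split-R̂ diagnostics and
  95% credible intervals.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Simulate a noise-free subject on the 4°-peak-to-peak PRTS and compare the
estimated frequency response with the closed-form loop response:

```python
import numpy as np
from posturolab import (
    TernaryDesign, build_prts, BalanceModelParams, simulate_sway,
    segment_cycles, estimate_frf, estimate_coherence, analytic_frf,
)

design = TernaryDesign()                      # 80-step, 20-s PRTS cycle
stim = build_prts(design, 1.78, n_cycles=4)   # "pp4": 4 deg peak-to-peak
print(f"peak-to-peak tilt: {np.ptp(stim.samples):.3f} deg")

subject = BalanceModelParams()                # 66.8 kg, delayed PID, w_prop=0.4
rec = simulate_sway(stim, subject, seed=1)

cycles = segment_cycles(rec, stim.cycle_duration, discard_first=True)
fr = estimate_frf(cycles, stim.excited_frequencies)
coh = estimate_coherence(cycles, stim.excited_frequencies)
H = analytic_frf(subject, stim.excited_frequencies)

print("freq_hz  gain   phase_deg  coherence  |H|_analytic")
for f, g, p, c, h in zip(fr.freqs, fr.gain, fr.phase, coh, np.abs(H)):
    print(f"{f:7.2f}  {g:.3f}  {p:9.1f}  {c:9.3f}  {h:12.3f}")
```

Output:

```
peak-to-peak tilt: 4.005 deg
freq_hz  gain   phase_deg  coherence  |H|_analytic
   0.05  1.629       -3.3      1.000         1.629
   0.15  1.666      -29.4      1.000         1.665
   0.25  1.599      -55.2      1.000         1.595
   0.35  1.377      -80.2      1.000         1.372
   0.45  1.104     -100.6      1.000         1.100
```

The stimulus integrates to 4.005° peak-to-peak (the designed 9-step ×
0.25 s × 1.78 °/s excursion). Gain peaks (≈1.67) at 0.15 Hz — the body
sways more than the platform near resonance — with growing phase lag
toward higher frequencies; the estimate matches the analytic response to
a few tenths of a percent, and coherence is 1.000 because this run is
noise-free. The same chain applies unchanged to measured recordings read
with `read_recording`.

The full synthetic session — calibration, pre/post PRTS blocks with
bootstrap CIs, 75 learning trials and hierarchical trends for all nine
per-trial metrics — runs as

```bash
posturolab run --seed 1 --outdir results/session
```

or programmatically via `posturolab.run_protocol(SessionConfig(...))`.

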