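# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the design was genuinely open,
and what the synthetic cohort can and cannot stand in for.

## Stimuli

**Pseudo-random ternary sequence (PRTS).** Platform tilt velocity is a
maximal-length sequence over GF(3) mapped to {−v, 0, +v}. The default
design has register order m = 4 (period 3⁴ − 1 = 80 symbols), step
duration 0.25 s, hence a 20-s cycle. The recurrence aₙ = aₙ₋₁ + aₙ₋₄
(mod 3) with symbol map {0→0, 1→+1, 2→−1} was selected by enumerating all
eight primitive degree-4 recurrences and both nonzero symbol mappings and
keeping a configuration whose cumulative-sum excursion is 9 steps. With
that excursion, nonzero velocities of 0.44, 0.89 and 1.78 °/s integrate to
peak-to-peak tilt amplitudes of 0.99, 2.0025 and 4.005° — the classic
"pp1/pp2/pp4" pairings (each within 0.01° of the nominal 1/2/4°). A
"maximal-length" 81-step ternary sequence does not exist (3ᵐ − 1 is never
81); the 80-step design is the one whose integrated amplitudes land on the
standard velocity pairings, so an 81-step description is read as a
fencepost count of step boundaries.

The symbol DFT is exactly flat across the odd harmonics of 1/20 Hz and
exactly zero at even harmonics; the integrated position spectrum therefore
decays as 1/f over odd harmonics only. A harmonic counts as *excited* when
its position-spectrum amplitude is at least 10% of the largest harmonic
amplitude (default threshold, configurable). For the default design this
yields 0.05, 0.15, 0.25, 0.35 and 0.45 Hz. The threshold rule avoids
hand-listing the structurally null (even) harmonics.

**Rhythmic learning stimulus.** An 8-s superposition of 1-Hz and 1.25-Hz
sines (8 and 10 integer cycles). The printed constraints — extremes 5.3°
toes-down and 2.6° toes-up — under-determine the five free parameters, so
the solver fixes both phases at 0, imposes a zero-velocity start
(f₁a₁ + f₂a₂ = 0) and solves (a₁, offset) for the extremes:
a₁ = 2.22830°, a₂ = −1.78264°, offset = −1.35°. The zero-velocity start
also lets the simulator begin trials in equilibrium, so trials carry no
onset transient beyond the stimulus's own dynamics. Sign convention
everywhere: toes-up positive.

**Sample rate.** 100 Hz by default; all PRTS step and cycle boundaries
fall on samples at this rate.

## Sway simulator

A single inverted pendulum linearized about upright,

J θ̈ = m g h θ + T,  T(t) = [K_p e + K_d ė + K_i ∫e](t − τ) + n(t),
e = w_prop·u + r − θ,

where u is platform tilt, r the lean set-point, and the error mixes a
proprioceptive channel (body-to-platform, weight w_prop) with a
graviceptive channel (body-in-space, weight 1 − w_prop) in the
independent-channel tradition of sensory-feedback balance models. The
closed-form stimulus response

H(f) = w_prop·PC/(1 + PC), P = 1/(J s² − mgh), C = (K_p + K_d s + K_i/s)e^{−τs}

is the package's exact oracle: the time-domain integrator must reproduce
it, and the whole FRF estimation chain is validated against it (2% gain,
2° phase at all excited harmonics on noise-free data; observed agreement
is ~0.3% / 0.1°).

Defaults (declared simulator conventions, not fitted values): body mass
66.8 kg, height 1.73 m, COM height 0.56·height = 0.969 m, rod-like inertia
(4/3)mh², K_p = 850 N·m/rad, K_d = 280 N·m·s/rad, K_i = 10 N·m/(rad·s),
delay τ = 0.15 s, w_prop = 0.4. These place the closed-loop gain peak
(≈1.7) near 0.15 Hz, inside the 0.1–0.3 Hz band characteristic of tilt
posturography, and keep the loop comfortably stable. Stability is verified
by a 12-s noise-free release from a 1° offset whose envelope must decay;
an unstable configuration raises an error naming the gains and the
divergence, and any running simulation aborts with a "simulated fall"
error if |θ| exceeds 30°.

**Integration.** Fixed step at 10× the recording rate (1 kHz internally).
The plant is discretized exactly per substep via the matrix exponential
with the torque held constant over the substep (zero-order hold); the
delay is an integer-substep ring buffer; the error integral uses the
trapezoid rule; the stimulus is linearly interpolated to the internal rate
(exact for the piecewise-linear PRTS). The residual discretization error
is the half-substep hold lag, ≈0.36° of phase at 2 Hz — an order of
magnitude inside the oracle tolerance. Trials start at the equilibrium for
the initial stimulus value (the integral state pre-loaded with the
gravity-cancelling torque), which matters for the 8-s learning trials
where an onset transient would leak drift into the low-frequency bins.

**Noise.** Torque noise is white noise through a first-order low-pass
(default time constant 1 s), scaled to a stationary SD of `noise_sd` N·m —
a 1/f-like random-sway background. Default cohort level 1.5 N·m yields
realistic coherences and feedback scores in the 100–500 range. COP sensor
noise is white with SD `cop_noise_sd` (default 0.5 mm in cohorts).

**Measurement channels.** Markers come from a two-segment geometry (legs
0.32 of body mass, COM at 0.55 of the 0.530·height leg segment; HAT 0.68
of mass, COM at 0.543 of the 0.288·height trunk segment — whole-body COM
height 0.56·height). A small slow hip-bend oscillation (0.2° at 0.04 Hz,
random phase) is superposed for calibration realism; the leg angle is then
solved exactly so the two-segment COM reproduces the pendulum COM. COP is
computed from the ankle torque balance, cop = h·sinθ − Jθ̈/(mg), which
equals the COM projection exactly in static conditions — the premise of
the calibration routine.

**Learning cohort.** Default 19 subjects × 75 trials. Trial-to-trial drift
(exponential, time constant 25 trials): lean set-point 3.3° → 2.4°, and
proprioceptive weight shrinking by √0.67 so the stimulus-evoked sway
*power* falls by 33% — mirroring the reported learning-phase effect sizes.
Because w_prop scales only the stimulus path (the postural feedback of θ
always has total weight 1), noise-driven sway is constant across trials by
construction: the low-frequency PSD is genuinely held fixed, giving the
trend model a known null alongside known negative slopes. Between-subject
dispersion: SD 0.4° on set-points, 0.04 on w_prop, 6% on K_p. All
randomness derives from one master seed via splittable seed sequences.

## Calibration

OLS of COP on (hip, shoulder) translations with an intercept
(statsmodels). The intercept is included although a pure two-segment model
needs none; it absorbs common-mode offsets harmlessly and is exercised by
the affine-equivariance property test. Collinear markers (no hip bend) are
rejected via the smallest singular value of the centered design.
Conversion to angle uses arcsin of translation/height. On noise-free
synthetic data the fit recovers the geometry's exact coefficients to
machine precision and calibrated COM tracks the simulator truth channel to
≪0.05° RMSE; with 20-dB COP sensor noise coefficients stay within 5%.

## FRF and coherence

Recordings are reshaped into stimulus cycles; the first cycle of each
trial is discarded against transients (17 of 18 cycles per trial, 323
pooled across a 19-subject cohort). Per cycle, the DFT ratio
R(f)/S(f) is formed at excited harmonics and averaged across all pooled
cycles (cycles pooled across subjects per condition, matching the
bootstrap's cycle pool); gain = |mean ratio|, phase = unwrapped angle in
degrees with lag negative, anchored so the lowest harmonic lies in
(−180°, 180°]. Coherence is magnitude-squared with cycle-averaged cross-
and auto-spectra; it is exactly 1 for noise-free linear responses, has
expectation ≈1/N for stimulus-independent sway over N cycles (verified by
Monte-Carlo), and needs ≥2 cycles. Frequencies where the stimulus carries
no energy are dropped with a warning. Logarithmic band-averaging is
provided for display only; raw per-harmonic values are always retained.
The linear simulator cannot reproduce the empirical decrease of gain with
stimulus amplitude — that is a sensory-reweighting nonlinearity outside
this model class, and the estimators are validated on amplitude-invariant
gains instead.

## Learning-trial metrics

Per 8-s trial: linear regression of the COM trace (intercept at t = 0 =
starting position; slope = drift, °/s); the residual's single-sided DFT
amplitudes (2|X_k|/N) on the 0.125-Hz grid up to 2 Hz (16 bins); PSD
partition into stimulus bins (1.0, 1.25 Hz), low bins (0.125, 0.25 Hz)
and the 12 remaining bins, with full = stim + low + high exactly; the
feedback score fb = Σ|y(k)|·100 + |s|·1000 with a component labelled
dominant only strictly above 70% of the score; and stimulus-frequency gain
and phase combined across the two stimulus bins by stimulus-amplitude
weighting (per-frequency values available). The summation grid starts at
0.125 Hz — an 8-s window has no finer bin, so a printed lower bound of
0.0125 Hz is treated as a typographical slip. The full-spectrum PSD is
capped at 2 Hz for consistency with the feedback score.

One caveat discovered while testing: a pure sine starting at phase 0 is
antisymmetric about the window midpoint and therefore correlates with the
linear regressor (continuous-time slope −6A/(πkT)); "detrending leaves a
zero-mean sine untouched" holds only for components even about the window
midpoint, and the tests are written accordingly.

## Bootstrap

Cycles are resampled with replacement (same pool size), the statistic is
recomputed per replicate, and limits are read element-wise from the
ascending sorted replicates at positions round(n(1∓ci)/2) — the
10th/390th of 400 for 95%. Resampling by subject exists as an option but
is off by default; no simultaneous-band correction is applied. Coverage on
a Gaussian-mean toy is 0.95 ± 0.03 over 500 replications and CI width
shrinks as 1/√n.

## Hierarchical trend model

y_ij = (β₀ + b0_i) + (β₁ + b1_i)·seq_j + ε_ij with correlated subject
effects, seq coded from 0. Priors: Normal(0, 10) on β; Half-Cauchy(0, 2)
on both group-level SDs; uniform on the correlation (the one prior the
formulation leaves open) and, by symmetry, Half-Cauchy(0, 2) on the
residual SD. The subject effects are marginalized analytically
(per-subject covariance σ²I + XΣXᵀ handled by the Woodbury identity on the
2×2 Σ), leaving a 6-dimensional posterior over (β₀, β₁, log sd₀, log sd₁,
atanh ρ, log σ) sampled with emcee's affine-invariant ensembles — several
independent ensembles serve as chains, walkers initialized near the
per-subject OLS summary. Defaults: 4 chains × 4000 iterations (2000
warm-up) × 16 walkers; a reduced preset (2 × 1000/500) serves repeated
recovery studies. Split-R̂ is computed per parameter across chains; R̂ >
1.05 flags non-convergence with a warning (noise-free degenerate data
deliberately trip this flag while still pinning the slope). A slope is
"significant" when its 95% credible interval excludes 0. Parameter
recovery: ≈95% CI coverage of a configured slope and ≈5% false-positive
rate under a zero-slope generator (200 replications each); the
intercept-slope correlation posterior tracks the realized correlation of
the 19 subject draws — at that cohort size the sampling noise of the
correlation itself (SD ≈ 0.12) dominates any estimator error.

## End-to-end protocol

`run_protocol` chains calibration → pre PRTS (3 amplitudes) → 75 learning
trials → post PRTS → metrics → bootstrap CIs → trends, with per-stage
seeds split from the master seed and a manifest carrying config hash and
output-file hashes (identical config + seed ⇒ byte-identical manifests).
The post-measurement uses each subject's end-of-learning set-point and
weight, so post FRF gains sit below pre gains. The end-to-end acceptance
run uses 5 PRTS cycles, 100 bootstrap replicates and the reduced sampler
preset — enough to resolve the configured signature (significant negative
stim-PSD and starting-position trends, flat low-frequency PSD) at desk
scale; the full-size defaults remain the package defaults.

## What the synthetic cohort does not show

The simulator is linear and time-invariant within a trial: it cannot show
gain decreasing with stimulus amplitude, threshold/dead-zone estimator
effects, explicit sequence prediction, startle responses, or multi-link
dynamics beyond the calibration hip wobble. Passing tests demonstrate that
the estimators recover known ground truth under realistic noise — not that
human cohorts behave like the generator.
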