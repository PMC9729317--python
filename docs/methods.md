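# Methods

This note records the models, conventions and open design choices behind
plrkit, module by module, and what the simulated backends do and do not
capture about real hardware and real pupils.

## Spectral computation (`plrkit.spectra`, `plrkit.cie`)

All spectral quantities are rectangle-rule sums Σ value·weight·Δλ over the
spectrum's own grid restricted to the overlap with the weighting function,
with Δλ the local grid step.  One consequence worth stating explicitly: the
number of *samples*, not intervals, sets the value — a unit spectrum times a
unit weight over 400–500 nm at 1 nm steps integrates to 101.  The default
grid is 380–780 nm at 1 nm; out-of-band power is ignored (the hazard
computation uses the hazard table's native 300–700 nm support).

Weighting functions are generated from closed forms rather than shipped as
tables:

* **CIE 1931 2° colour-matching functions** use the piecewise-Gaussian
  analytic fits of Wyman, Sloan & Shirley (2013), accurate to about 1% of
  peak; small negative lobes of the fit are clipped at zero.  Equal-energy
  white therefore lands within ~0.005 of (1/3, 1/3).
* **V(λ)** is the fitted ȳ renormalised so V(555 nm) = 1 exactly, making
  the monochromatic 555 nm → 683 lx anchor hold by construction.
* **α-opic action spectra** (S-, M-, L-cone-opic, rhodopic, melanopic) use
  the Govardovskii et al. (2000) A1 pigment template (α + β bands) placed at
  the standard corneal peak wavelengths 440/545/570/510/490 nm, unit peak.
  These reproduce peak positions and bandwidths of the standardised
  functions but not their tabulated values to the last digit (no explicit
  ocular-media pre-filtering).  Absolute α-opic irradiances of broadband
  sources computed here should be treated as model quantities; within the
  package they are self-consistent, which is what calibration and matching
  require.  Tests of the integration machinery use synthetic narrowband
  weights so they do not depend on table provenance.
* **Blue-light hazard B(λ)** embeds the photobiological-safety standard's
  5 nm table (300–700 nm; 10^((450−λ)/50) between 500 and 600 nm, 0.001
  above), interpolated linearly to the working grid.

Hazard limits: for exposures t ≤ 10⁴ s the dose L_B·t is compared against
10⁶ J·m⁻²·sr⁻¹; for longer exposures L_B against 100 W·m⁻²·sr⁻¹; both are
divided by the pupil correction factor (actual/3 mm)² ≥ 1.  Full precision
is stored; only report text truncates to one decimal (100/6 → 16.6), the
convention used when such limits are quoted.

## Light engine and simulated backends (`plrkit.engine`)

`DeviceSettings` is ten integers in [0, 4095]; normalisation is s/4095 so
the maximum maps to exactly 1.  `VideoFile` is a documented stand-in JSON
dialect ({metadata, frames: [{time_ms, settings[10]}]}, ".dsf" extension) —
not a bit-compatible clone of any vendor format, whose schema is
proprietary.  Frames closer than the device's 10 ms switching floor are a
validation error rather than being silently coalesced.

The simulated engine is additive over channels: dark + Σ betaCDF(sᵢ/4095;
αᵢ, βᵢ)·primaryᵢ + Gaussian noise, clamped at zero.  Default primaries are
ten Gaussians peaking 420–660 nm with 24 nm FWHM and 0.02 W·m⁻²·nm⁻¹ peak
spectral irradiance — roughly the layout and photometric scale (hundreds of
lux at maximum) of a 10-channel research light engine viewed in an
integrating sphere.  Not modelled: thermal drift, channel interaction,
command latency, spectral shift with drive level.

The simulated spectrometer reads counts = value·gain·t_int + dark(T, t_int)
+ noise, with a dark model *linear* in both PCB temperature and integration
time (defaults: 30 + 0.5·T°C + 0.1·t_ms counts; gain 1000 counts per
W·m⁻²·nm⁻¹·ms; 14-bit full scale).  Real spectrometer dark behaviour is
device-specific and not published for any particular unit; the linear model
makes the correction step explicit and exactly invertible when noise is
off.  The same coefficients are shared with the calibration correction, so
dark correction is by model inversion, not by paired dark frames.
Dark-corrected values are *not* clipped at zero: clipping would bias
low-light calibration levels upward (the lookup clips at query time
instead).  Saturation is flagged in metadata, and saturated readings are
excluded from calibration with a log message.

## Calibration (`plrkit.calibration`)

The sampling plan is multiples of the step in [1, 4095]; the default step
65 gives 63 evenly spaced levels ending exactly at 4095 (63·65 = 4095).
Level 0 is optional — when absent, interpolation is anchored at (0, zero
spectrum), since dark-corrected output at zero drive is physically zero
(logged when applied).

`build_context` interpolates spectra linearly over intensity, per
wavelength, onto the full 0–4095 integer grid.  Illuminance, α-opic and
unweighted-irradiance lookups are linear functionals of the spectrum, so
they are computed at the knots and interpolated with the same rule; with a
twice-differentiable channel curve the worst-case lookup error shrinks at
second order in the plan step (verified empirically, fitted order ≥ 1.8).

`fit_curves` fits betaCDF(s/4095; α, β) to normalised illuminance by
unweighted least squares (the loss is a package choice; nothing forces a
weighting), bounded to α, β ∈ [10⁻³, 10²], initialised at (1, 1) — the
identity curve.  A channel with no measurable output raises a fit error
naming the LED.  `optimise_profile` is the exact inverse:
round(4095·betaCDF⁻¹(desired)); the forward/inverse round trip is within
two 12-bit steps across [0.01, 0.99].

## α-opic matching (`plrkit.matching`)

Matching operates on the five α-opic irradiances, never on full spectra:
two stimuli matched this way produce the same photoreceptor excitations
even if their spectra (and chromaticities) differ.  Column j of the 5×10
matrix A is LED j's α-opic vector at maximum divided by 4095 — a linearity
assumption that is exact for the linear simulated engine and an
approximation otherwise.  Both solvers keep box bounds [0, 4095]: the
"unconstrained" label sometimes attached to local optimisation in this
problem sits poorly with a bounded 12-bit drive, so bounds are enforced and
the choice documented here.  Rounding to integers happens after
optimisation, and the reported residual is recomputed post-rounding through
the calibrated forward model, so it reflects the deliverable stimulus.
Because A has a 5-dimensional row space and 10 columns, distinct settings
with identical α-opic output exist (the solver's null space); which one is
returned is solver-dependent and immaterial for the match criterion.
`scale_stimulus` scales in the linearised output domain (forward through
the fitted curve, multiply, invert), clipping to the gamut with a warning.

## Onset timestamping (`plrkit.stamper`)

Detection is the signed difference of whole-frame pooled mean intensity
between consecutive frames, strictly exceeding the threshold — onsets only,
since stimuli are timestamped at onset; an `absolute` flag enables offset
detection.  Pooled versus per-channel means differ only by a threshold
rescaling for this decision rule.  Frames are reduced to their mean at
ingestion; the algorithm uses no spatial structure.  Timeouts count stream
time, not wall time, so tests are deterministic.  The asynchronous variants
return `concurrent.futures.Future` objects from a dedicated thread, which
is what lets two cameras be stamped concurrently for cross-camera
synchronisation checks.  Operating-system-dependent camera timestamp
offsets (tens of ms on some platforms) are represented only as the
configurable constant of `apply_timestamp_offset` (default 0); no clock
synchronisation is emulated.

## Preprocessing (`plrkit.preprocess`)

* Eye selection: highest mean confidence; ties go to eye 0.
* Masking: a sample is missing when the first derivative *into* it deviates
  from the derivative's mean by more than 3 SD, or when confidence is
  strictly below 0.95 (at-threshold samples are retained).  The SD is of
  the *derivative*, over the whole recording — the wording "first
  derivative exceeded ±3 SD" admits either reading; the derivative's own SD
  is used because blink transients live in the derivative.  Derivatives are
  time-aware (Δvalue/Δt) to tolerate eye-tracker sampling jitter.
* Interpolation: linear in time for interior gaps; leading/trailing gaps
  take the nearest valid value (linear interpolation is undefined there).
* Filtering: 3rd-order Butterworth at 4 Hz applied zero-phase
  (forward–backward).  Zero-phase is chosen because a causal filter's group
  delay would bias the latency estimate; the cost is that the effective
  magnitude response is squared — gain at the cutoff is 1/2, not 1/√2 —
  which is tested against |H(f)|² = 1/(1+(f/4)⁶).
* Trials: 5 s before to 65 s after each onset, %-change against the 5 s
  pre-stimulus baseline mean.

## Parametrisation (`plrkit.metrics`)

Latency is the time of the acceleration minimum in (0, t_peak], computed
with the compact three-point second difference (a repeated-gradient second
derivative widens the stencil and shifts the estimated onset a frame
later).  T75 is interpreted as recovery of 75% of the *constriction
amplitude* from peak toward baseline (threshold peak + 0.75·(baseline −
peak)); the alternative reading — 75% of resting size — is available via
`recovery_fraction`.  The constriction-onset time used for the average
constriction velocity is the latency point.  Velocities are signed
(constriction negative).  A trial with no constriction is flagged
degenerate with all parameters NaN; a trace that never reaches the recovery
threshold in-window leaves T75 NaN.  Session summaries exclude NaN values
per parameter and report the exclusion count; SD for a single defined value
is reported as 0.

On noiseless synthetic trials at 120 Hz, recovery accuracy across a 3×3×3
grid of amplitude × latency × recovery-τ is: baseline and peak within 1%,
latency within 2 frame intervals, T75 within 5% of its closed form τ·ln 4.
On *filtered* data the latency estimate is biased late by roughly the
smoothing kernel's half-width (~0.1 s at 4 Hz for the C¹ synthetic onset),
because zero-phase smoothing spreads the acceleration transient
symmetrically into the response; real constrictions are smoother than the
synthetic kink, so the bias there is smaller but not zero.  Optional
upsampling before latency estimation is deliberately not implemented;
frame-interval precision (8.3 ms at 120 Hz) is the documented floor.

The PIPR sustained metric is the mean %-change over a configurable late
window, default 10–30 s after stimulus *offset* (onset + stimulus duration,
default 1 s); the blue-minus-red difference of this metric is the
melanopsin signature.

## Synthetic ground truth (`plrkit.synthetic`)

The pupil waveform is flat baseline B; after the latency, a C¹ smoothstep
descent of amplitude A over the constriction duration; then exponential
recovery toward B − f·A with time constant τ (f = sustained fraction).  The
smoothstep makes the peak time exact and places the negative acceleration
peak at the constriction onset, so latency has an unambiguous ground truth;
a C² (smootherstep) onset would move the acceleration peak into the
interior of the constriction.  For f < 0.25 the 75% recovery time is
T75 = τ·ln((1−f)/(0.25−f)).

Defaults echo adult PLR scale — baseline 5.5 mm, amplitude 2.7 mm, latency
0.25 s, constriction over 1 s, τ = 3 s, 120 Hz, 0.05 mm measurement noise —
used for realism, never as analysis ground truth (every generator returns
its truth bundle alongside the data).  Blinks are Poisson-placed collapses
toward zero over 50–150 ms with confidence dropped to 0.1; the morphology
is a pragmatic stand-in and only its maskability is asserted.  Session
fixtures are binocular, with eye 1 a noisier, lower-confidence (0.90) copy
so confidence-based eye selection has a planted answer; trials are spaced
80 s apart with onsets jittered 5–10 s after a cue, and sustained
constriction is eased back to baseline between trials.  PIPR sessions plant
sustained fractions of 0.10 (blue) vs 0 (red), i.e. an expected sustained
contrast of −100·0.10·A/B ≈ −4.9% change.

What the generators do *not* emulate: photoreceptor-driven dynamics (no
ipRGC model — the sustained fraction is imposed, not derived from melanopic
irradiance), pupil unrest/hippus, foreshortening artifacts, 3D-model
refitting jumps, or gaze-dependent confidence.  Passing tests therefore
demonstrate that the *pipeline* recovers what the waveform model plants,
not that the model captures pupil physiology.

## Problem sizes

Test and acceptance runs use desk-scale problem sizes chosen to exercise
every code path: the full 63-level calibration plan; 20 random settings for
forward-model checks; 50 random in-gamut matching targets; a 27-point
noiseless recovery grid; 20 noisy trials for the NaN-exclusion rule; and
5–10 simulated six-trial PIPR sessions (~8 min of 120 Hz binocular data
each) for the end-to-end contrast.
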