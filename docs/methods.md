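# Methods

`ippgsim` renders synthetic skin-patch videos in which every physiological
and optical component is known exactly, then closes the loop by recovering
the pulse with the classical imaging-photoplethysmography (iPPG) methods
and scoring the recovered heart rates against the embedded ground truth.
This note records the models, the defaults that matter, the numerical
choices, and what the simulator does and does not claim about real videos.

## Signal model

Each rendered pixel follows a multiplicative illumination model over a
three-layer skin description:

    C(t, x, y) = clip( I(t) · [ b · tex(x, y) + s·c(t) + m(t) ] + N(t, x, y) )

- `b` — static base reflectance (R, G, B) of the melanin/base-color layer,
  selected by a six-class skin-tone preset (I lightest … VI darkest, luma
  strictly decreasing).
- `tex(x, y)` — static multiplicative surface texture: seeded white noise
  smoothed over ~3 px, relative contrast 0.05, floored at 0.1.
- `c(t) = (β_r, β_g, β_b) ⊙ P(t)` — the pulsatile subsurface color with
  channel weights β = (0.33, 0.77, 0.53) applied to the unit-normalized
  pulse `P(t) ∈ [0, 1]`; the scalar pulse scale `s` defaults to 0.01
  (≈1% green-channel modulation, representative of real skin). In the
  default *additive* mode the subsurface term adds to reflectance, so its
  absolute amplitude is tone-independent; a *multiplicative* mode
  (`pulse_mode`) makes the pulse ride on the base reflectance, so darker
  tones carry proportionally smaller absolute pulse amplitudes — this is
  the melanin-attenuation mechanism behind dark-skin recovery errors and
  the mode used by the tone-comparison tests.
- `m(t)` — an achromatic (equal in all channels) specular/motion artifact,
  see below.
- `I(t)` — strictly positive relative illumination: a constant I₀ under
  stable laboratory light, or profile/event-driven (step, ramp, sinusoid,
  scenario events).
- `N` — i.i.d. zero-mean Gaussian camera noise per pixel and frame, added
  after the illumination scaling (sensor noise is post-optics);
  σ defaults to 0.002 on the [0, 1] intensity scale (≈0.5 LSB at 8 bits).

8-bit quantization uses round-half-up; the static texture and the camera
noise act as natural dither, so spatial averaging recovers sub-LSB pulse
amplitudes the way real cameras do.

## Pulse waveform

One PPG beat is four key-points — wave onset, systolic peak, dicrotic
notch, diastolic peak — placed at fixed fractions of each inter-beat
interval (IBI). The default template is (time fraction / relative
amplitude): onset 0.00/0.00, systolic 0.25/1.00, notch 0.45/0.55,
diastolic 0.60/0.65. Key-points are joined by a shape-preserving monotone
piecewise-cubic interpolant (PCHIP), which passes through every key-point
exactly and cannot overshoot between them, so each beat has exactly one
systolic maximum; one phantom beat is padded at each end to stabilise the
boundary. Heart-rate variability is a sinusoidal modulation of the
instantaneous IBI,

    IBI(t) = (60/HR) · (1 + d·sin(2π f_mod t)),

evaluated at each onset (first onset at t = 0). The reference
configuration is HR = 70 beats/min, f_mod = 0.3 Hz, 25 Hz sampling; the
modulation depth d defaults to 0.05 (a documented package default — only
the modulation frequency is a reference value).

## Involuntary motion

Two sources compose `m(t)`:

- **Ballistocardiographic neck rotation**, locked to the heart rate: one
  sinusoid period per cardiac cycle with per-cycle amplitude drawn from
  Normal(0.12°, 0.03°) truncated at zero. The fundamental is exactly
  HR/60 Hz; the cycle-wise amplitude redraw spreads sidebands around it.
- **Breathing** at a frequency drawn once per video from the physiological
  0.13–0.4 Hz band (8–24 breaths/min): phase-aligned sinusoids moving head
  and shoulders vertically and the chest horizontally (inhale = up /
  forward), default amplitudes (0.02, 0.015, 0.01) scene units.

Because this is a patch-level simulator (no geometry), motion is projected
to intensity by a zero-mean linear map `m(t) = Σ g_k (trace_k − mean)`.
The default BCG gain (0.0045 intensity units per degree) makes the motion
artifact's standard deviation ≈20% of the green-channel pulsatile
amplitude — visible without burying the pulse. Slow postural sway
(<0.5 Hz) is deliberately out of scope; only the high-frequency BCG
component is modelled. The motion phase is independent of the pulse phase.

A consequence worth stating plainly: an artifact locked to the heart rate
adds spectral energy *at the heart-rate frequency itself*, so it cannot
displace the spectral peak that the GREEN method's windowed estimator
reads out — GREEN is structurally robust to this particular artifact. The
chrominance methods, by contrast, show genuine nonlinear failures at large
motion gains: the per-window mean normalization of CHROM/POS turns a large
additive achromatic term into intermodulation products (pulse ± motion
frequencies) because the division leaks `m/b_channel` unequally per
channel. In this patch-level model the motion-robustness ordering of the
methods is therefore *inverted* relative to videos with geometric motion,
where the region of interest itself moves and GREEN degrades first.
Motion-induced degradation of GREEN does appear here, but through the
scenario pathway (in-band illumination events during physical activity),
not through the heart-rate-locked specular term.

## Scenarios and action coding

Actions are scheduled on the frame grid, either periodically (events at
frames `i·step`, `i = 0 … int(M/step)−1`) or non-periodically (a cursor
advances by a step drawn uniformly from {1…j} and inserts an event at each
new position; a zero step would stall the loop, hence the draw excludes
it). Each pattern is a transient multiplicative illumination perturbation
and/or motion-gain boost with a raised-cosine envelope. The four
benchmark scenarios:

| scenario | events | illumination |
|---|---|---|
| stable | none | constant I₀ |
| expression_talk | non-periodic expressions (±2–8%), periodic blinks (1 per 4 s) | event-perturbed |
| light_change | non-periodic ramps, 10–40% toward darkness and back | event-perturbed |
| physical_activity | periodic gait events (every 12 frames → ≈2.1 Hz at 25 fps, in-band), 3× motion gains | event-perturbed |

## Extraction methods

All methods take the spatial-mean R, G, B traces of the region of interest
(the full patch by default) at the video frame rate. The cardiac band is
0.7–4.0 Hz (42–240 beats/min), 3rd-order zero-phase Butterworth.

- **GREEN** — linear detrend + band-pass of the green trace.
- **ICA** — JADE (fourth-order cumulant joint diagonalization, implemented
  in `ippgsim.jade`) on z-scored channels; components ordered by explained
  variance; the *second* component is returned by convention, with the
  most in-band component recorded in the diagnostics. Rank-deficient
  input falls back to in-band spectral selection with a warning.
- **CEEMDAN** — complete-ensemble empirical mode decomposition with
  adaptive noise (Torres variant, implemented in `ippgsim.emd`; ensemble
  100, relative noise 0.2, seeded). The returned IMF is the one whose
  dominant frequency lies in the cardiac band with the highest in-band
  energy; an optional minimum in-band fraction makes selection strict and
  raises an explicit no-pulse-found error otherwise.
- **CHROM** — per 1.6-s window (50% overlap) the channels are normalized
  by their window means and projected to X = 3Rₙ−2Gₙ, Y = 1.5Rₙ+Gₙ−1.5Bₙ;
  the stitched X, Y are band-passed at full length (filtering inside a
  1.6-s window would destroy fundamentals near the 0.7 Hz band edge), then
  per window S = X_f − α·Y_f with α = σ(X_f)/σ(Y_f), Hann overlap-add.
- **POS** — per 1.6-s window, temporally normalized channels projected on
  the plane axes (0, 1, −1) and (−2, 1, 1), tuned
  S = S₁ + (σ₁/σ₂)·S₂, mean-removed, Hann overlap-add, band-passed.
  A window at least as long as the signal reduces exactly to the
  single-window computation.

Both chrominance methods cancel achromatic flicker identically (the α and
σ₁/σ₂ tuning make the cancellation exact, not just approximate).

## Heart-rate estimation and metrics

Heart rate is computed every 10 s (non-overlapping windows; a trailing
partial window is dropped) as 60× the in-band peak of a mean-removed,
Hann-tapered, 4×-zero-padded periodogram (bin ≈ 1.5 beats/min at 10 s; the
physical resolution of a 10-s window is 6 beats/min). Errors are the RMSE
over windows and the per-window percent error |P−T|/T·100. Benchmarks
pool windows within a scenario×method cell. Failed extractions become
NaN rows with diagnostics, never aborts.

## Determinism

A single master seed fans out through `numpy.random.SeedSequence` into
fixed named streams (beat timing, motion, scenario, camera noise,
breathing draw), so disabling one component never shifts another's draws,
and identical configurations reproduce bit-identical frames and reports.

## Problem sizes

The package's reference experiments run at desk scale by choice: 64×64
patches at 25 fps for 60 s (the full 640×360 geometry is available through
the configuration), six videos for the stable-scenario method comparison,
and a 4-rate × 3-seed sweep for rate recovery. At these sizes all five
methods stay well under 1 beat/min RMSE in the stable scenario.

## What the simulator does not show

Passing closed-loop tests demonstrates internal consistency of the
model + methods, not field performance: the patch has no facial geometry,
no region-of-interest tracking errors, no compression artifacts, no
specular highlights with spatial structure, and its motion enters as a
scalar intensity term rather than optical flow. The channel weights β are
held constant across skin tones although physically they co-vary with
melanin; this is flagged as future work. Results on real videos will be
worse and differently ordered — notably the motion robustness of GREEN
discussed above.
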