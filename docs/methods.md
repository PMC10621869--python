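# Methods

This note documents the models, numerical choices and limitations behind the
pipeline; the README gives the stage-by-stage overview.

## Synthetic ECG generator

The generator is a statistical surrogate for overnight single-lead ECG, built
to exercise every pipeline stage, not to be physiologically faithful. Each
segment is a sum of five Gaussian bumps per beat (P, Q, R, S, T) at fixed
offsets relative to the R peak (−0.20, −0.035, 0, 0.035, 0.22 s; amplitudes
0.15, −0.12, 1.0, −0.20, 0.30; widths 45, 12, 20, 14, 70 ms), sampled at
100 Hz. Beat times come from integrating an instantaneous heart-rate profile
f(t) = (bpm/60)·(1 + depth·sin(2πt/T)) on a fine grid and firing a beat at
every integer phase crossing, so the modulation shapes beat *timing*, the way
cyclic bradycardia–tachycardia accompanies repetitive obstructive events.
White measurement noise (SD relative to R amplitude 1) and an optional 50 Hz
interference tone are added last; everything is a deterministic function of
the config and seed (per-segment seeds derive from the master seed through
`SeedSequence` spawn keys, so datasets are order-independent).

Defaults, fixed as the simulated study conditions: 60 bpm mean rate, 60 s
segments, modulation period 45 s, noise SD 0.05, no power-line tone, and
record-class modulation depths A = 0.4, B = 0.2, C = 0.0. Class B is defined
only as "borderline" severity in the AHI taxonomy, so an intermediate depth is
the natural surrogate. What the generator does **not** emulate: realistic QRS
morphology variation, ectopic beats, electrode artifacts, respiration or SpO₂
coupling, and record-length recordings with mixed apnea/normal epochs. Passing
tests therefore demonstrate that the pipeline recovers a known low-frequency
beat-timing contrast, not clinical performance on real ECG.

## Multirate front end

Filter order, ripple and transition width are free parameters; the defaults
are 101 taps, passband edge 30 Hz, stopband edge 35 Hz, ≥40 dB attenuation
(verified at design time, with an error advising a larger order if the spec is
missed). Filtering is offline: direct-form convolution followed by (M−1)/2
group-delay compensation, zero-padded at the edges, so output sample n aligns
with input sample n. The fractional decimator evaluates a natural cubic spline
through the samples at t = nD, anchored at sample 0; for a 6000-sample input
and D = 1.5625 the output has ⌊5999/1.5625⌋+1 = 3840 samples at 64 Hz.
Constructing a `ResampleSpec` with D above fs/(2·f_max) raises immediately.

## Wavelet band selection

The DWT is a 4-level db4 cascade with symmetric half-point extension
(PyWavelets). The four analysis bands are named Delta/Theta/Alpha/Beta with
ranges 0–4/4–8/8–16/16–32 Hz. One subtlety is documented in the `decompose`
module: at a 64 Hz input rate the dyadic bands are d1 = 16–32, d2 = 8–16,
d3 = 4–8 and a3 = 0–4 Hz — the conventional labels a4/d4/d3/d2 cover the named
ranges only for a 128 Hz input. The package is frequency-faithful: under each
band label it selects the coefficient sequence that actually covers that
band's range at the working rate (Delta = level-3 approximation, recombined
from the level-4 pair by one inverse DWT step; Theta = d3; Alpha = d2;
Beta = d1). The raw 4-level coefficients are retained so analysis/synthesis
round-trips are lossless (checked to 1e−8).

EMD is applied to the selected coefficient sequences themselves, not to
band-limited reconstructions at the full rate — the bands are fed onward
exactly as extracted.

## Empirical mode decomposition

Extrema are strict neighbor-comparison extrema with plateaus collapsed to
their center sample. Envelopes are cubic splines through the maxima (upper)
and minima (lower), with up to two extrema mirrored past each end to suppress
boundary swings; fewer than four usable knots degrades gracefully to linear
interpolation. Sifting iterates h ← h − (upper+lower)/2 until the Cauchy
criterion SD = Σ(h_prev−h)²/Σh_prev² < 0.2 *and* the extrema/zero-crossing
counts differ by at most one, capped at 100 sifts per IMF. Decomposition stops
after five IMFs, or earlier when the running residue becomes monotonic; missing
IMFs are zero-padded (and flagged) so every band always yields exactly five
IMF slots. Reconstruction Σ D_m + r_4 = z is exact by construction and asserted
to 1e−9 relative error. Constant input returns five zero IMFs with a warning.

## Hjorth features

The derivative is the unnormalized first difference: mobility and complexity
are ratios, so a constant sampling step cancels, and activity does not involve
the derivative at all. Variances use the 1/N denominator, stated so tests are
bit-stable. Zero-variance inputs (padded IMFs) produce (0, 0, 0) triples with
a degenerate flag rather than an error, keeping the 15-feature contract
(5 IMFs × activity/mobility/complexity, IMF-major order) intact. The optional
per-feature significance screen is a two-sided Mann–Whitney U test at
α = 0.01, chosen because it is distribution-free — Hjorth activities are
heavily right-skewed. It is reported only; no feature is ever dropped by it.

## Classifier and optimizer

Default architecture 15 → 32 (tanh) → 2 (softmax), cross-entropy loss,
mini-batches of 32, 200 epochs, Glorot-uniform initialization; all of it
seeded and configurable. Features are z-scored with training-split statistics
(stored on the model) because raw Hjorth activities span orders of magnitude
across IMFs. Adam uses α = 0.01, β₁ = 0.9, β₂ = 0.999, ε = 1e−8, moments
initialized to zero, standard bias correction by (1−βᵗ), and ε added after the
square root in the denominator. A `literal_bias_correction` flag switches to a
variant that divides by (1−β) without the step exponent and derives the
corrected first moment from the second-moment accumulator; it exists for
side-by-side comparison only, as that recursion is not a consistent
first-moment estimate. Prediction is score argmax with ties broken toward the
first class (documented, deterministic).

## Evaluation

Accuracy, sensitivity, specificity and precision are percent ratios of
confusion counts; F1 is the harmonic mean of precision and sensitivity. The
kappa index uses observed agreement = accuracy and chance agreement from the
products of the confusion marginals (Cohen's convention — the verbal
definition leaves the chance term open), reported ×100 so 95.00 means κ = 0.95.
Any ratio with a zero denominator is reported as NaN and named in the report's
`undefined` list, never silently coerced to 0; a constant predictor yields
exactly κ = 0.

## Experiment runner

Four binary tasks (A vs B, A vs C, B vs C, apnea vs normal) × four bands. The
severity tasks label every segment of a record with the record's AHI class;
apnea-vs-normal uses per-minute annotations. Two split modes are exposed —
record-wise 50/50 (whole records on one side only) and stratified segment-wise
— because pooled-segment and per-record protocols give different numbers and
both are defensible; the synthetic default is the stratified segment split.
Every report row carries the hash of the config that produced it. A band whose
features are degenerate for all segments is marked failed and the run
continues.

## Problem sizes and tolerances

Reconstruction identities are asserted at 1e−9 (EMD, relative) and 1e−8 (DWT,
absolute on unit-scale noise). Closed-form Hjorth checks run on 100-period
sinusoids at 64 Hz (activity 0.5 ± 1e−6, mobility 2·sin(πf/fs) ± 1e−3,
complexity 1 ± 0.02). The Adam recursion matches an independent plain-float
scalar implementation to 1e−12 over 100 steps. The end-to-end synthetic
experiment uses 100 segments per class with a fixed seed; the null experiment
(both classes unmodulated) bounds its best-band accuracy below 70%, the 3σ
binomial band around chance at a 100-segment test split.

## Known limitations

- The synthetic class contrast is beat-timing only; discrimination on real ECG
  also involves morphology and artifact structure the generator omits.
- The WFDB reader supports single-segment format-16 records and N/A per-minute
  annotations — sufficient for the target database layout, not a general WFDB
  implementation.
- EMD uses plain sifting; no ensemble variants, so mode mixing on noisy real
  data is possible.
- No cross-validation or hyperparameter search; the runner exposes exactly the
  two split protocols described above.
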