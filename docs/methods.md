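# Methods

## The measurement model

Pulse arrival time (PAT) is the delay between ventricular depolarization
(ECG R-peak) and the arrival of the pressure pulse at a peripheral site
(here, the onset of the finger-PPG upstroke). It is the sum of the
pre-ejection period and the pulse transit time; only the latter carries the
arterial-stiffness/pressure signal, and the two cannot be separated with
ECG + PPG alone — this package therefore treats PAT as a single surrogate
and never attempts pre-ejection-period decomposition.

The working model is a locally linear inverse coupling between PAT and
systolic pressure,

    PAT(t) = PAT₀ − k · (SBP(t) − SBP₀),    k ≈ 1 ms/mmHg,

which motivates (a) inverting the PAT change (iCPAT = −ΔPAT) so that its
sign matches the BP change, and (b) testing *equivalence* of iCPAT (ms) and
ΔBP (mmHg) on a shared ±5 scale rather than mere correlation. Equivalence
uses the paired TOST construction: with d = iCPAT − ΔBP,

    p₁ = P(T₍ₙ₋₁₎ > (d̄ + 5)/(s/√n)),   p₂ = P(T₍ₙ₋₁₎ < (d̄ − 5)/(s/√n)),

declaring equivalence iff max(p₁, p₂) < α = 0.05. A zero-variance sample is
treated as a point mass (p = 0 on each side whose boundary the mean
strictly clears). By default the two intervals per session are pooled into
one observation set; a config flag computes per-interval TOSTs instead.

Assumptions worth stating: the coupling is assumed stationary within a
session (no drug- or posture-induced recalibration), the two signal streams
share one clock, and hour-period averages are long enough that
respiratory and beat-level fluctuations are negligible after smoothing.

## Extraction chain and numerical choices

**R-peaks.** A Pan–Tompkins-style detector: zero-phase band-pass 5–15 Hz
(2nd-order Butterworth, `sosfiltfilt`), derivative, squaring, 150-ms
moving-window integration, running signal/noise threshold
(thr = N + 0.25·(S − N), exponential updates with weight 1/8), 200-ms
refractory period, and refinement of each detection to the local raw-ECG
maximum. Zero-phase filtering keeps the integrator peaks aligned with the
QRS so the refinement window (±100 ms) is symmetric.

**Pulse onsets (intersecting tangents).** The segment between an R-peak
and min(next R-peak, +0.6 s) is smoothed with a 10-ms moving average
(edge-renormalized), the slope is the central first difference of the
smoothed segment, the steepest-ascent point is the slope argmax (first
occurrence on ties), the diastolic level is the minimum of the smoothed
segment up to that point, and the onset is the abscissa where the tangent
at the steepest point meets that level. On piecewise-linear pulses all
these operations are exact, so the fiducial equals the breakpoint to
machine precision; this is the basis of the onset-exactness tests. Beats
with no positive slope, or an intersection outside the segment, are
flagged (`no_upstroke`, `onset_out_of_range`) rather than dropped
silently.

**Pairing.** Each R-peak takes the first onset in (r, r + w], with
w = min(next RR, 0.6 s); each onset is consumed at most once; unpaired
beats are flagged. PAT = (onset − r)·1000 ms.

**Plausibility filter.** Thresholds are exposed as config with defaults
RR ∈ [0.3, 2.0] s, PAT ∈ [100, 500] ms, and a beat-to-beat jump limit of
30 ms against the median of the 5 nearest range-valid beats. The published
filter this emulates does not print its constants; these defaults bracket
a typical dialysis cohort (PAT ≈ 233 ± 42 ms) by a wide margin. The
filter's verdicts are recomputed from the raw values on every call (flags
from other sources are preserved), which makes it idempotent by
construction.

**Smoothing.** For each valid beat at time t the smoothed PAT is the
Hann-weighted mean, w(Δ) = cos²(πΔ/180 s) on |Δ| ≤ 90 s, over valid
beats, with weights renormalized where the window is truncated at the
record edges (no zero-padding, hence no bias toward zero). The window
preserves constants exactly and attenuates a 0.25-Hz respiratory
oscillation by more than 20×; its purpose is to remove respiratory sinus
arrhythmia before hour averaging.

## Periods, changes, exclusions

Recordings often stop before the nominal 4 h, so the three 1-hour
averaging periods are anchored to the PAT recording span: beginning =
first 3600 s, end = last 3600 s, middle = 3600 s centred on the recording
midpoint, truncated to non-overlap for recordings under 3 h (under 2 h the
middle period is empty and the session is excluded). A `clock` mode using
fixed dialysis hours is available; whether the "middle hour" should be
recording-centred or clock-defined is genuinely open, and the
recording-centred default was chosen for robustness to early termination.

Changes are later-minus-earlier period means; relative changes are
percentages of the earlier period's mean (the natural baseline reading).
Sessions are excluded when they have < 6 cuff readings, any empty hour
period (PAT or BP), or — as a reproducible proxy for manual ECG-quality
review — fewer than 50% valid beats after filtering. The
intradialytic-hypotension rule takes the session's first cuff reading as
the initial SBP and flags an interval when any raw reading in its later
period falls below 90 mmHg (initial < 160) or 100 mmHg (initial ≥ 160).

## Classification

Observations (two per retained session), not patients, are the unit.
Labels come from the relative BP change with a strict ±2% band
(exactly ±2% is stable); the binary task is decliner vs (stable + riser).
The fixed-threshold predictor mirrors the BP rule at +2% relative PAT
change — the operating point is a config choice, not an estimate; the ROC
analysis is threshold-free. F1 is the harmonic mean of precision and
sensitivity; AUC is the trapezoidal area, which the tests pin to the
Mann–Whitney pairwise-concordance statistic exactly, ties counted ½.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, one
seeded `numpy` generator end to end:

* **Beat schedule**: RR(t) = 60/HR · (1 + a·sin(2πf·t)) with a = 5% and
  f = 0.25 Hz (typical respiration).
* **BP trajectories**: piecewise-linear, designed as plateau-per-period
  curves so the three hour means (and hence the designed relative changes)
  are exact by construction. Designed relative changes per interval are
  drawn uniformly from (−10, −4)% for decliners, (−1, +1)% for stables and
  (+4, +10)% for risers — magnitudes well clear of the ±2% labelling band
  on both sides, so design labels are unambiguous while measured labels
  still carry realistic cuff-noise ambiguity.
* **PAT**: PAT(t) = PAT₀ − k·(SBP(t) − SBP₀) plus Gaussian beat jitter
  (default 3 ms).
* **Cuff readings**: gap times uniform in [900, 1200] s (12–16 readings in
  4 h), Gaussian measurement noise (default 3 mmHg).
* **Waveforms**: ECG as Gaussian R-deflections (σ = 10 ms) on a flat
  baseline; PPG pulses with a flat diastolic foot, a *linear* systolic
  upstroke blending into a quarter-cosine shoulder at half the 150-ms rise
  time, and an exponential decay rescaled to reach the baseline before the
  next foot. The linear-rise shape is deliberate: the steepest-ascent
  tangent then passes through the true onset, so the intersecting-tangents
  fiducial analytically equals the designed onset and recovery tolerances
  are provable. (A raised-cosine upstroke, by contrast, puts the tangent
  intersection at onset + rise·(1/2 − 1/π) ≈ +27 ms for a 150-ms rise —
  a shape-induced bias, not a detector error.)
* **Artifacts**: dropouts (both channels to baseline for 1–5 s), ectopic
  beats (extra R-deflection at 0.4·RR), PPG spikes; 2 events/h by default.
* **Covariates**: age ~ N(64.9, 18.1²) years, 34% female, height
  ~ N(172, 10²) cm, weight ~ N(78, 15²) kg.

What it does **not** emulate: real PPG morphology (dicrotic notch,
amplitude modulation), baseline wander, motion artifact spectra,
pre-ejection-period dynamics, ultrafiltration physiology, or
within-session coupling drift. Passing tests therefore demonstrate that
the *pipeline* is correct and well-calibrated under its stated model, not
that the clinical effect sizes would reproduce on real patients.

## Problem sizes and calibration experiments

The default cohort is 30 sessions (10 decliner / 10 stable / 10 riser,
4 h each) analysed at beat level, which keeps a full pipeline run around
five seconds; full waveform rendering plus extraction is exercised on
single sessions (about four seconds per 3-h session at 512 Hz). The TOST
type-I experiment uses 10 000 replicates of n = 20 at the +5 margin with
sd = 5. On noisy waveforms the intersecting-tangents onset acquires a
positive, noise-dependent bias (the slope argmax selects upward noise
excursions); the bias is approximately constant within a session and
cancels in the period-mean *changes* the analysis consumes, but absolute
PAT values from noisy records should not be interpreted as calibrated.
Measured class labels include cuff noise, so decliner-detection F1 on the
default cohort varies with the seed; occasional values below 0.9 reflect
label noise in stable sessions near the ±2% band, not predictor failure.

## Known limitations

* The equivalence margin equates milliseconds and mmHg through an assumed
  1 ms/mmHg coupling; patients with different vascular compliance shift
  this scale.
* The exact plausibility-filter constants and the manual quality-review
  criteria of the emulated workflow are not published; both are exposed as
  configuration rather than fixed truths.
* Waveform I/O is delimited text only.
* No multiple-testing correction is applied across the statistical battery,
  matching the analysis design this package implements.
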