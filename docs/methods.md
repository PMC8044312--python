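# Methods

## The screening model

The package operationalizes a simple physiological claim: ischemic
myocardium repolarizes heterogeneously, so the T wave's *area* varies from
beat to beat, while a healthy ventricle produces nearly identical T waves
for minutes at a time.  The pipeline therefore measures, per lead, the
beat-to-beat fluctuation of the baseline-corrected T-wave area over a
15-second resting recording (~20 sinus beats) and declares the subject
positive when any lead fluctuates beyond a calibrated threshold.  The method
assumes sinus rhythm (no ectopy, flutter or fibrillation), heart rate above
about 50 bpm, and a recording long enough to yield at least 8 usable beats
per lead.

## Delineation

**R peaks** are detected on lead II (configurable; fallback: largest
peak-to-peak lead) by band-pass filtering (5–18 Hz, zero-phase), squaring,
moving-window integration (120 ms), peak picking with a 300 ms refractory
distance, and refinement to the raw-signal extremum within ±60 ms.  One R
train is shared by all leads.

**Search windows.**  The T-boundary search window for beat *i* is a
piecewise function of the preceding RR interval with three cases:

| target | case 1 | case 2 | case 3 |
|---|---|---|---|
| onset  | RR < 0.67 s | 0.67 ≤ RR < 1.23 s | RR ≥ 1.23 s |
| offset | RR < 0.71 s | 0.71 ≤ RR < 1.10 s | RR ≥ 1.10 s |

Each bound is `R + round(coeff × RR_samples) + fixed`, with ceil rounding in
cases 1 and 3 and floor in case 2.  Coefficients (onset `a..f` = 0.4, 0.2,
0.4, 0.4, 0.3, 0.0; offset 0.2, 0.1, 0.2, 0.0, 0.0, 0.1) and fixed offsets
(onset +0.02/+0.16, +0.04/+0.24, +0.04/+0.40 s; offset +0.18/+0.30,
+0.18/+0.40, +0.18/+0.48 s) ship as defaults.  Two numerical conventions
are deliberate choices:

* the coefficient product is rounded **in samples** — rounded in seconds,
  floor would collapse to zero for every RR below 2.5 s and the coefficients
  would be inconsequential;
* case boundaries belong to the upper case (case 2 is closed below, open
  above).

With these published coefficients the onset case-3 window is degenerate
(`t1 ≥ t2` for every RR ≥ 1.23 s: `ceil(0.3·RR) + 0.04 > 0.40` throughout
the case).  Such beats are skipped with a log entry rather than silently
mislocated; re-tuning the coefficients via `tune_window_params` is the
remedy for long-RR recordings.  Windows whose R-to-boundary interval leaves
the admissible per-case range are logged but still searched.  The first beat
of a record has no preceding RR and uses the record's median RR.

**Boundary localization.**  The indicator at candidate `t` is
`A(t) = Σ_{k=t−W+1..t} (s_k − s_t)` (trailing; offsets) or its time mirror
(leading; onsets); the boundary is the argmax of |A| over the window, ties
to the earliest sample, and an identically zero indicator flags the beat as
having no T wave.  Subtracting `s_t` cancels constant offsets exactly and
makes the statistic polarity-agnostic.

The indicator window length is not prescribed by the window equations and is
exposed in `IndicatorConfig`.  Two failure modes bound it.  A window much
longer than the T wave makes |A| flat after the true offset, so localization
within the search window becomes noise-driven.  Conversely, once
`W·s_peak` exceeds the T area, candidates near the T apex dominate |A| and
capture the argmax away from the boundary.  The two searches face this
trade-off differently: under the shipped window coefficients the *offset*
search window never begins near the T apex, so its indicator can span the
whole T wave and localize the end essentially exactly (default
`window_w = 0.040 s`), while the *onset* search window can reach the apex
and needs a short window (default `window_w_onset = 0.020 s`, about one T
up-slope).  Both stay below the 0.05 s minimum admissible R-to-onset
interval.

## T-wave area and the curve

For each delineated beat, `A = Σ_{t=T_on..T_off} (s_t − s̄)` over the closed
interval, in raw mV·samples (optional normalization to mV·s).  The local
baseline `s̄` is the mean of a `2·round(p·fs)+1`-sample window (default
`p = 0.016 s`, 33 samples at 1 kHz).  The printed form of the baseline
window's limits is ambiguous; the package's default places the window
**ending at the T onset** (a pre-T isoelectric estimate), with a centered
placement available as `BaselineConfig(placement="centered")`.  The
preceding placement was chosen because the search-window geometry forces the
T apex within a few tens of milliseconds of the onset: the right half of a
centered window then overlaps the T up-slope, coupling the baseline estimate
— and hence the area — to per-beat delineation jitter; in cohort simulations
this artifactual fluctuation was comparable to the area itself and destroyed
the healthy/ischemic contrast, while the preceding placement leaves areas
insensitive to boundary jitter of several samples.  Shift invariance (adding
a constant to a lead changes nothing) holds identically for both placements.

Areas are kept signed — inverted T waves (aVR) give negative areas, and sign
crossings of the curve are reported (`sign_flips`) because they are
clinically notable.  Missing beats stay missing (NaN); nothing is
interpolated.

## Decision rule

Per lead, `score = median(|A_{i+1} − A_i|) / (median(|A_i|) + 1e−9)`,
successive differences taken only between adjacent beats that are both
present.  The normalized median absolute successive difference is robust to
single outlier beats and invariant to lead gain.  A lead needs ≥ 8 usable
beats (a 15 s record at the 50 bpm bradycardia floor yields ≥ 12).  The
subject is positive iff any lead's score exceeds the threshold; positive
leads map to advisory artery hints (V3/V4/aVL → left anterior descending,
aVR → left main/circumflex, others unlocalized) that never change the
decision.

The shipped threshold 0.1706 maximizes the Youden index on the packaged
synthetic cohort (seed 0, n = 100, prevalence 0.5); on that cohort the
classes separate completely (healthy scores ≤ 0.12, ischemic ≥ 0.21).  It is
a property of the synthetic study conditions — users screening real ECGs
should recalibrate on labelled data with `calibrate_threshold`.

## Calibration utilities

`fit_search_boundaries` clusters (RR, R-to-boundary) pairs with k-means
(k = 3 by default, seeded, optional coordinate standardization — off by
default); RR case thresholds are midpoints between adjacent clusters' RR
extents and per-case boundary ranges are cluster min/max.
`tune_window_params` exhaustively traverses a per-coefficient grid,
scoring each combination by boundary sensitivity (fraction of reference
boundaries recovered within ± tolerance, default 20 ms) under seeded k-fold
cross-validation (default fivefold); ties break to the first combination in
lexicographic grid order.

## Synthetic data

Beats are sums of five Gaussians (P, Q, R, S, T); defaults: P (0.12 mV,
−0.20 s, σ 20 ms), Q (−0.08, −0.03, 8 ms), R (1.1, 0, 10 ms), S (−0.15,
+0.03, 8 ms), T (0.30 mV, +0.285 s, σ 6 ms), heart rate 100 bpm with 10 ms
RR jitter.  The T Gaussian is truncated at ±3σ and those truncation points
*are* the ground-truth onset/offset, so delineation error is measured
against an exact reference.  The default T timing and width were chosen by
analysis of the shipped search-window equations so that, at the default
heart rate, both true boundaries fall inside the windows the published
coefficients generate (at RR ≈ 0.6 s the onset window is roughly
R+0.26–0.28 s and the offset window R+0.30–0.36 s, which forces a compact T
with its apex between the two windows).  One beat template is shared across
leads with per-lead amplitude scales; aVR's scale is negative, producing the
physiological inverted complex.  Upright, inverted and biphasic
(Gaussian-derivative) T morphologies are available.

Ischemia is emulated as record-wide per-beat T-amplitude modulation
`exp(η)`, `η ~ N(0, σ_v)` — log-normal, so the mean area over many beats is
`exp(σ_v²/2)` times the unmodulated area (a tested property).  Cohort
defaults: σ_v = 0.35 for positives, 0.02 for negatives, white noise 0.01 mV,
baseline wander 0.05 mV at 0.25 Hz, 15 s at 1 kHz, prevalence 0.5.  The
positive σ_v is a free parameter standing in for an effect the source data
describe only qualitatively ("jagged" curves); it was fixed once at a value
giving clearly irregular curves, not tuned against any test.

What the generator does **not** emulate: ST-segment shifts, ectopy and
non-sinus rhythms, respiratory modulation, electrode artifacts, inter-lead
timing differences, or realistic T-wave durations (the published search
windows admit only a compact T at the default heart rate).  Passing
synthetic tests therefore demonstrates the pipeline's internal correctness
and its sensitivity to beat-to-beat repolarization variability — not
clinical performance; the printed clinical sensitivities cannot be
reproduced without the hospital recordings and the (unoperationalized)
visual "jagged" criterion.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: cohorts of
40–100 subjects (15 s, 12 leads, 1 kHz), five records per noise level for
delineation error, 1000 random windows for the locator/brute-force
equivalence, ~5800 beats for the log-normal mean check.  Every stochastic
step takes an explicit seed (NumPy `SeedSequence` spawning per subject);
fixed seed implies bit-identical records and byte-identical pipeline
artifacts.

## Known limitations

* Only WFDB format 16 and the text dialect are read; other ADC formats and
  units are rejected rather than guessed.
* The onset case-3 window is unusable with the published coefficients (see
  above); bradycardic records (RR ≥ 1.23 s) lose their onsets unless the
  coefficients are re-tuned.
* The decision threshold and the minimum-beat rule are calibrated to the
  synthetic study conditions.
* Localization hints are advisory lead-set lookups, not an electrophysiological
  model.
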