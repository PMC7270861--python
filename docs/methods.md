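# Methods

## Scope and data model

`walkbeat` analyses wearable recordings of a standardized six-minute
walking test (6MWT) performed five times over a cardiac-rehabilitation
program (three weeks between tests).  A session is a single-lead ECG at
512 Hz plus a triaxial accelerometer at 32 Hz, annotated with three
phases: 300 s rest, 360 s walk, 300 s recuperation, with time t = 0 at
the start of rest.  Since no clinical recordings ship with the package,
a synthetic cohort generator produces raw waveforms with full ground
truth; all cohort-level results are recoveries of that generative truth
through the complete signal chain.

## Synthetic cohort generator

### Group structure

Two response groups defined by total distance gain over the program
relative to a 90 m split:

| parameter | low-response | high-response |
|---|---|---|
| patients | 44 | 45 |
| baseline distance | N(496, 95²) m | N(473, 97²) m |
| total gain | mean 55 m, SD 25, < 90 m | mean 147 m, SD 25, > 90 m |
| walk kinetics (a, b), session 0 | (−1.3·10⁻⁴, 6.5·10⁻²) | (−2.7·10⁻⁵, 2.2·10⁻²) |
| walk kinetics, session 4 | unchanged | equal to low group |
| recovery time constant τ | 90 s all sessions | 90 → 30 s linearly |

Gains are sampled from a one-sided truncated normal whose
*post-truncation* mean equals the declared group mean: the declared
value is the observed mean of a group that by definition lies on one
side of the split, so a naively truncated N(55, 25²) would
systematically undershoot it by ≈ 4 m.  The location parameter is
solved numerically (Brent) and samples are drawn by inverse CDF.

Per-session distances interpolate monotonically from baseline to
baseline + gain with jittered inner fractions (SD 0.05, sorted), so the
final-minus-baseline difference is exactly the sampled gain.

### Heart-rate trajectory

Instantaneous HR is piecewise: constant `rest_hr` during rest; the
quadratic rest_hr + b·u + a·u² during the walk (u = seconds from walk
onset, so the walk starts at the resting rate — continuity); and an
exponential decay from the end-of-walk rate back toward `rest_hr` with
time constant τ during recuperation.  The coefficient units follow the
convention that the fitting abscissa is seconds from phase onset; the
default group-level values above were chosen so that group-mean fitted
coefficients are the quantities the pipeline must recover.  The high
group's walk coefficients interpolate linearly toward the low group's
across sessions (the "catching up" pattern), while its recovery τ
shortens; the low group is stationary in both.

### Heterogeneity and noise

* Per patient (constant across sessions): rest HR ~ N(70, 3²) bpm;
  multiplicative N(1, 0.1²) factors on a and b (independent) and on τ.
  These SDs are package choices — within-group coefficient variances are
  not observable from group-level summaries — set so that between-patient
  spread is visible but group means remain estimable at n ≈ 44
  (SE ≈ 1.5 % of the mean).
* Per beat: RR intervals are generated as RR_k = 60 / (HR(t_k) + ε_k)
  with ε_k ~ N(0, hr_noise_sd²), hr_noise_sd = 2 bpm by default, plus a
  2 % multiplicative RR jitter; RR is clipped to the physiological
  [0.3, 2.0] s.  Modelling the noise at the beat level (white across
  beats) is deliberate: it averages out within the 16-s analysis windows
  like real beat-to-beat variability, rather than acting as correlated
  window-level error that no windowing could remove.
* The rest-HR SD of 3 bpm is narrower than clinical between-patient
  variability; it keeps recovery-minute group contrasts detectable at
  the modest effect sizes the walk-phase coefficients imply under the
  seconds-based unit convention.

### Waveforms

ECG: one QRS-T template per beat (Gaussian Q/R/S plus a T wave), R peak
within one sample of the beat time; additive baseline wander, broadband
noise (SD 0.03 of the unit R amplitude), and by default two 3-s
saturation bursts per session pinned at the amplifier rail, recorded in
the ground-truth artifact spans.  Accelerometer: gravity on z plus
sinusoidal gait components at 1.8 Hz whose amplitudes scale linearly
with an intensity parameter that rises identically for both groups
across sessions (1.0 + 0.1·session m/s²), so effort increases over the
program without a group difference.

Everything derives from a single integer seed via `SeedSequence` spawn
keys `(group, patient)` and `(group, patient, session)`, so any subset
of the cohort can be regenerated independently and identically.

### What the generator does not emulate

Real ECG morphology variation (P waves, ectopy, arrhythmia), electrode
motion artifact beyond saturation bursts, circadian or medication
effects on HR, dropout, and any within-patient session-to-session drift
other than the modelled trends.  Passing tests therefore demonstrate
correctness of the processing chain and statistics under a plausible
generative model — not clinical performance on hospital data.

## Signal processing

* **Segmentation** slices both channels at the annotated phase
  boundaries (sample counts must match the layout within one sample).
* **Artifact detection** is a signal-quality stand-in with the contract
  downstream needs, not a re-implementation of any published method:
  per non-overlapping 2-s window a window is flagged if it is flat
  (SD < 10⁻⁸), if more than 5 % of its samples exceed 1.8× the robust
  typical peak amplitude (median of per-window maxima of |x − median|,
  so a minority of saturated windows cannot inflate the reference), or
  if the normalized autocorrelation peak in the 0.25–1.6 s lag range
  falls below 0.10 (no quasi-periodic QRS energy).
* **R-peak detection** is Pan-Tompkins-style: 2nd-order Butterworth
  band-pass 5–15 Hz (zero-phase), derivative, squaring, 150-ms moving
  integration, candidate peaks with a 250-ms refractory distance, and
  adaptive signal/noise levels (initialized from the first 2 s,
  exponential update 0.125/0.875, threshold = noise + 0.25·(signal −
  noise)).  Each detection is refined to the band-passed maximum within
  ±100 ms.  Beats inside flagged windows are marked `excluded`.
* **Beat correction** replaces visual review with a deterministic,
  idempotent rule: an RR below 0.3 s deletes the later beat (spurious
  double detection); an RR above 2.0 s or deviating more than 30 % from
  the running median of the last 7 accepted RR intervals keeps the beat
  but flags it `corrected`, removing it from HR computation without
  interpolation.

## Features

Mean HR over a span is 60 / mean(RR) over RR intervals fully inside the
span, using only `detected` beats (intervals longer than 2 s, which can
only arise by spanning removed stretches, are discarded).  The static
spans (20 s rest tail, 10 s walk tail, 60 s recovery minutes) are
evaluated directly in the beat domain — a 2-min analysis window cannot
resolve a 10-s span, so the literal span definitions take precedence.
Windowed HR series support 120-s and 16-s windows with a 4-s stride;
kinetics fitting uses the 16-s series, which resolves within-phase
dynamics over a 6-minute phase where the 2-min window cannot.  Windows
without a complete RR interval are gaps and are omitted.

Effort removes the per-axis mean over the walk phase (the gravity
component, without which the statistic is dominated by the constant 1 g
offset and could not increase with walking intensity) and averages the
Euclidean norm over all n walk-phase samples; the mean (not the sum)
normalization makes the value duration-independent.

## Kinetics fitting

Candidate families, fitted on (t, HR) with t in seconds from phase
onset: `one_term_exp` α·e^{βt}; `two_term_exp` α·e^{βt} + γ·e^{δt};
`two_term_exp_offset` α·e^{βt} + γ; `quadratic` a·t² + b·t + c.  The
quadratic is solved by linear least squares on the Vandermonde system;
exponentials by bounded nonlinear least squares (`scipy` curve_fit,
≈ 200 evaluations per free coefficient) with data-driven starts (first
value, log-linear slope; the offset family starts as a decay from the
first toward the last value).  Non-convergence yields a fit marked
failed with a diagnostic, never an exception.  R² = 1 − SSres/SStot
with the degenerate conventions SStot = SSres = 0 → 1 and SStot = 0 <
SSres → −∞ (numerically-zero residuals, below 10⁻¹² of the signal
energy, count as zero).  Family selection maximizes mean R² over the
supplied fits; ties prefer fewer free coefficients, then lexicographic
order.  Series must have no gap longer than 60 s and at least one more
point than free coefficients.

## Statistics

* Group split: gains strictly above the threshold (90 m default, or the
  sample median) are `high`; ties go `low`.
* Compliance: 100 · attended / 9 per inter-test interval.
* Outliers: boxplot rule, linear-interpolation quartiles, fences at
  Q1 − 3·IQR and Q3 + 3·IQR, strict inequality — with IQR = 0 nothing is
  removed.  Applied within each group × session cell; deletions then
  propagate to per-parameter listwise deletion (each parameter's ANOVA
  keeps only patients complete for that parameter, which is why error
  dfs can differ between parameters).
* Two-way mixed ANOVA: classical sums-of-squares partitioning
  (between-subjects: group, subjects-within-group; within-subjects:
  time, time×group, time×subjects-within-group as the error term).
  Partial η² = df_main·F/(df_main·F + df_error) for every emitted
  effect.  No sphericity correction by default — reported integer error
  dfs imply uncorrected tests — with Greenhouse–Geisser available as an
  option.  Follow-ups: one-way repeated-measures ANOVA within each
  group after a significant interaction; per-session contrasts by
  pooled-variance t or Mann-Whitney.  p-values come from the exact
  F / t / U null distributions.
* Baseline table: Shapiro-Wilk at α = .05 in each group decides
  mean (SD) + t versus median (IQR) + Mann-Whitney for continuous
  variables; binary categorical variables get n (%) and Fisher's exact
  test.

## Problem sizes and numerical checks

The test suite validates the ANOVA implementation against a brute-force
per-observation sums-of-squares oracle on hundreds of random balanced
designs (2–4 subjects per group, 2–5 sessions, 10⁻⁹ agreement) and
cross-checks one design against `pingouin`.  The quadratic solver is
checked against `numpy.polyfit` to 10⁻⁹.  Detection sensitivity is
scored on 500 simulated minutes of ECG (≥ 99 % clean, ≥ 95 % at 10 dB
SNR, ±20 ms matching).  Cohort-level recoveries run the default
89-patient, five-session cohort end-to-end from raw waveforms (about
two minutes on one CPU); unit tests use cohorts of 2–6 patients.
Noise-free identifiability (jitter and HR noise set to zero) recovers
each session's true quadratic coefficients to well under 5 % relative
error; with default noise, only group means (not per-patient values of
the tiny curvature coefficient) are recoverable, which matches how the
biomarkers are used.

## Known limitations

The artifact detector is a contract-level quality index, not a
validated clinical algorithm; the beat-correction rule approximates but
cannot reproduce expert visual review; the exponential families are the
standard curve-fitting forms matching their conventional names, which
matters little since the quadratic family wins selection on this data;
and all cohort-level numbers are simulation recoveries, not clinical
replications.
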