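# walkbeat

Wearable-ECG analysis of the six-minute walking test (6MWT) in cardiac
rehabilitation: from raw single-lead ECG (512 Hz) and triaxial
accelerometer (32 Hz) signals to static heart-rate parameters, an
accelerometer effort statistic, *digital cardiac biomarkers* from
heart-rate kinetics curve fitting, and the longitudinal comparison of
low- vs high-response patient groups — plus a fully seeded synthetic
cohort generator that stands in for clinical data and provides ground
truth for every processing stage.

## Who this is for

Researchers working with wearable ECG recordings of standardized
activity tests (rehabilitation follow-up, exercise physiology, digital
biomarker development) who need a tested, reproducible reference
pipeline; and methodologists who want a signal-to-statistics test bed
where every intermediate quantity has a known generative truth.

## The model

Each 16-minute session has three phases: 5 min seated rest, 6 min
walking, 5 min recuperation. After artifact masking, Pan-Tompkins-style
R-peak detection and automatic beat correction, the beat series yields:

* **Static parameters** — HR_rest (mean HR, final 20 s of rest),
  HR_peak (final 10 s of walking), HR_rec1..5 (each minute of
  recuperation), HR_peak-dist = HR_peak / distance, and effort = mean
  ‖(X,Y,Z)‖ of the DC-removed walk-phase acceleration.
* **Dynamic biomarkers** — the within-phase heart-rate series (16-s
  windows, 4-s stride) is fitted with four candidate families
  (one-term exponential, two-term exponential, two-term with offset,
  quadratic polynomial); the best family by R² is selected.  For the
  quadratic f(x) = a_poly·x² + b_poly·x + c, the coefficients a_poly
  (bpm/s²) and b_poly (bpm/s) characterize how fast the heart responds
  to exercise.

Patients are split into response groups at a 90 m total distance gain
(median split of the emulated cohort).  Each parameter's progression
over the five sessions is analyzed with a two-way mixed ANOVA (between:
group; within: session), effect sizes as partial
η² = df_main·F / (df_main·F + df_error), with repeated-measures
follow-ups and per-session t / Mann-Whitney contrasts, after
boxplot-rule outlier removal (> 3 box-lengths).

## Worked example

```sh
python examples/04_kinetics_biomarkers.py
```

```
family                r2
quadratic              0.9763  ok
two_term_exp_offset    0.9662  ok
one_term_exp           0.8287  ok
two_term_exp           0.8287  ok

selected family: quadratic
a_poly -0.000133 bpm/s^2 (truth -0.000122)
b_poly  0.0778 bpm/s   (truth  0.0716)
```

One simulated low-response baseline session was processed end-to-end
(ECG synthesis → R-peak detection → 16-s HR windows → model fits).  The
quadratic family explains the walking-phase heart-rate rise best, and
its fitted biomarkers land close to the generator's known truth for
this patient.  The other examples cover cohort simulation, R-peak
detection scoring, static session features, and the mixed-ANOVA group
comparison; each prints what it computes and what the numbers mean.

The command-line interface mirrors the stages:

```sh
walkbeat simulate --seed 1 --out sim/         # write session records
walkbeat process sim/low000_s0 --out beats.csv
walkbeat run --seed 1 --out report/           # full pipeline + report bundle
```

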