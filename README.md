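# phasemod

Transcranial alternating current stimulation (tACS) with waveforms derived
from a speech envelope can modulate how well a listener understands speech
in a cocktail-party situation.  `phasemod` is a Python package for the
computational side of such experiments: it synthesizes the stimulation
waveforms from audio, models how comprehension scores depend on the phase
shift between sound and current, analyzes the circular statistics of
per-subject best phases, and simulates the adaptive staircase used to set
each listener's speech reception threshold (SRT).  A synthetic-cohort
generator emulates the full experimental design, so every analysis can be
exercised end to end with known ground truth.

It is written for auditory neuroscientists and psychophysicists who want a
tested, reproducible reference implementation of this analysis chain.

## The model

Comprehension scores CS are measured at four phase shifts
φ<sub>n</sub> = n·90° of the stimulation waveform.  Scores are centered per
subject, ΔCS(φ) = CS(φ) − C̄S, and the cyclical dependence on phase is
decomposed as

```
ΔCS(φ) = A0 + A1·cos(φ − φ1) + A2·cos(2φ)
       = A0 + B1·sin(φ) + B2·cos(φ) + A2·cos(2φ)
```

with B2 = A1·cos φ1, B1 = A1·sin φ1, hence A1 = √(B1² + B2²) and
φ1 = atan2(B1, B2).  On four equispaced phases this is exactly a length-4
discrete Fourier transform of ΔCS, which the package uses as an internal
cross-check of the pooled regression.  The model is fitted by OLS and by
robust IRLS (Tukey bisquare), with Benjamini–Hochberg FDR correction of the
coefficient p-values and a subject-level bootstrap comparing the r² of the
two fitting methods.  Per-subject best phases are summarized with circular
statistics: resultant length R, angular deviation √(2(1−R)), the Rayleigh
uniformity test, a maximum-likelihood von Mises fit with Watson's U²
goodness of fit, and a two-sample concentration-homogeneity test.

The stimulation waveforms themselves are built from audio in five steps:
envelope (analytic-signal magnitude) → zero-phase Butterworth bandpass in
the theta range (4–8 Hz, order 6) → equalization of all extrema to ±1 →
phase shift via rotation of the analytic signal → peak scaling to the
calibrated current (mA).

## Worked example

```python
import phasemod as ph

scores = ph.generate_cohort(ph.CohortParams(seed=7))
fit = ph.fit_harmonic(ph.center_scores(scores, "target"), method="robust")
print(fit.coef.round(3))
print(f"A1 = {fit.A1:.2f} points, phi1 = {fit.phi1_deg:.1f} deg, "
      f"r2 = {fit.r2:.2f}, F = {fit.F:.1f}")
```

prints

```
    estimate  ci_low  ci_high  p_raw  p_fdr
A0    -0.027  -0.852    0.798  0.948  0.948
B1    -0.735  -1.901    0.432  0.217  0.434
B2     3.597   2.431    4.764  0.000  0.000
A2     0.386  -0.439    1.211  0.359  0.479
A1 = 3.67 points, phi1 = 348.5 deg, r2 = 0.35, F = 12.5
```

The cohort was generated with a true modulation of 3 percentage points
peaking at 0°: the fit finds a significant cosine component B2 ≈ 3.6 with
non-significant B1 and A2, i.e. a ~3.7-point modulation peaking near 0°
(348.5° ≡ −11.5°), and a centered intercept A0 at noise level.  The same
cohort's distractor-envelope condition peaks at 180°:

```python
from phasemod import circular as circ, phase_model as pm
best = pm.best_phase_per_subject(scores, "distractor")
summ = circ.circular_summary(best.to_numpy())
z, p = circ.rayleigh_test(best.to_numpy())
print(f"distractor best phases: mean {summ.mean_deg:.0f} deg, R = {summ.R:.2f}, "
      f"angular deviation {summ.ang_dev_rad:.2f} rad, Rayleigh p = {p:.3g}")
```

```
distractor best phases: mean 162 deg, R = 0.35, angular deviation 1.14 rad, Rayleigh p = 0.108
```

The full pipeline (both sources, OLS + robust fits, aligned refits,
bootstrap, circular analysis, sham ANOVA, report files and figures) runs
from a config:

```
phasemod simulate --seed 7 --out scores.csv
phasemod run --config run.yaml
```

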