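# Methods

This note documents the models, algorithms and numerical choices behind
`phasemod`, and what the synthetic-data generator does and does not
emulate.

## Waveform synthesis (`phasemod.waveform`)

The stimulation current is derived from audio in a fixed order: envelope →
theta bandpass → extrema equalization → phase shift → current scaling.

**Envelope.** Magnitude of the analytic signal (Hilbert transform) of the
broadband audio, optionally decimated.  Because the next stage keeps only
the 4–8 Hz band, the precise envelope estimator is non-critical; the
analytic magnitude is the standard choice.

**Theta bandpass.** Butterworth bandpass of order 6 (order-3 lowpass
prototype), 4–8 Hz, applied forward–backward (`sosfiltfilt`) for exact
zero phase.  Forward–backward filtering squares the magnitude response, so
the effective attenuation is twice the single-pass design; the package's
frequency-response oracle (`bandpass_gain`) reports the squared response
accordingly.  The sampling rate must exceed twice the upper band edge.

**Extrema equalization.** The band-limited signal is split at its zero
crossings and each half-cycle is divided by its own peak magnitude, so
every interior local maximum maps to +1 and every minimum to −1.  This
keeps zero crossings and extremum sample positions fixed, is continuous
(segments meet at zero), and is idempotent.  For signals whose extrema do
not alternate with zero crossings (secondary ripples within a half-cycle),
only the largest extremum of each half-cycle reaches ±1; theta-band
filtered envelopes are in practice well-behaved in this respect.

**Phase shift.** Rotation of the analytic signal:
y = x·cosθ − H{x}·sinθ.  Positive θ advances the phase (sin → cos at
+90°).  Multiples of 180° bypass the Hilbert path, so a 180° shift is
*exact* pointwise negation for arbitrary input.  For finite signals the
FFT-based Hilbert transform leaks DC/Nyquist terms, so composed shifts
agree with single shifts to a few percent of signal scale near the edges —
float-exact composition would require carrying the analytic signal through
the chain, which the stimulation hardware path has no use for.

**Sham.** A 500 ms pulse at sentence onset with 100 ms linear on/off
ramps (the ramp shape is not otherwise constrained; linear is the simplest
monotone choice).  The plateau sits at the calibrated current.

**Current scaling.** Peak-referenced: the waveform is scaled so its
absolute maximum equals the calibrated per-subject maximum current
(default 0.67 mA, the cohort mean of the skin-sensation calibration).
RMS-referenced scaling was considered and rejected: the calibration
procedure itself limits the peak, not the power.

## Harmonic phase model (`phasemod.phase_model`)

Scores are percent-correct keywords per subject × source × phase.  After
per-subject mean-centering over the four phases, the model

ΔCS(φ) = A0 + B1 sin φ + B2 cos φ + A2 cos 2φ

is fitted by one pooled regression over all subject × phase rows (72 at
study scale), with no subject random effects.  The 95% CIs come from the
coefficient covariance; p-values are FDR-corrected (Benjamini–Hochberg)
within each model's coefficient set (4 unaligned, 3 aligned).

**DFT equivalence.** On the balanced design the OLS solution equals the
length-4 DFT of the per-phase mean ΔCS: A0 = a0, B2 = 2·Re a1,
B1 = −2·Im a1, A2 = a2, with a_k = (1/4)Σ ΔCS e^(−ikπφ/180°).  Under this
forward transform ΔCS = A1 cos(φ − φ1) has a1 = (A1/2)e^(−iφ1), so
φ1 = −arg(a1) = atan2(B1, B2).  The mapping B2 = A1 cos φ1,
B1 = A1 sin φ1 is the unique one consistent with the trigonometric
expansion; it implies that a positive significant B2 with B1 ≈ 0 means a
modulation peaking at φ1 = 0°, and a negative B2 one peaking at 180°.
These identities are verified to float precision in the test suite.

**Robust variant.** IRLS with the Tukey bisquare loss at the standard
95%-efficiency tuning constant (c = 4.685) and MAD scale, iterated to
relative tolerance 1e−10 or 200 iterations (via statsmodels RLM).
Robust p-values are normal-approximation z-tests.

**r² and F.** r² is the squared Pearson correlation of observed and
fitted values over the observations the method *retains*: OLS retains all
rows; the bisquare fit assigns weight exactly zero to residuals beyond the
tuning constant, and those rejected rows are excluded from its r².  On
clean data nothing is rejected and the two computations coincide (where
OLS is optimal by construction); under gross contamination the robust r²
reflects the fit to the uncontaminated bulk.  An r² that kept the rejected
outliers could never exceed the OLS value, making the two methods
incomparable by design.  F is computed from this r² as
(r²/k)/((1−r²)/(n−k−1)) for both methods, so the robust fit gets an
F-statistic on the same footing.

**A1 confidence interval.** On the balanced design (B̂1, B̂2) is
approximately bivariate normal with independent components of common SE,
so Â1/SE follows a Rice distribution with noncentrality A1/SE.  The 95%
CI inverts that distribution exactly (a Wald interval for a vector norm
under-covers near the noise floor).  Above 40 SEs the Rice law is
numerically Gaussian and the Wald form is used.

**Bootstrap r² comparison.** Subjects are resampled with replacement
(each subject's full phase block stays together, preserving within-subject
structure; row resampling is available via `unit="row"`).  Both methods
are fitted to every resample and the paired r² values compared with a
one-tailed t-test of robust > standard.  Rank-deficient resamples are
skipped and counted.

**Best-phase alignment.** Per subject, the phase with the highest score
(ties → lowest phase) is removed and the remaining three ΔCS values are
re-indexed by (phase − best) mod 360; the aligned model drops the A2 term
because three points cannot identify four parameters.  Note the alignment
is a *selection* on the noise: even when every subject truly peaks at the
same phase, the aligned intercept is biased negative and the aligned
cosine term retains part of the true modulation.  Whether the aligned
refit is significant is therefore an empirical signal-to-noise question,
not a logical consequence of phase locking.

**Amplitude comparison between sources.** The construction of the
two-tailed test of the A1 difference is not uniquely determined by the
quantities it compares; here the observed difference of full-data A1
estimates is divided by the standard deviation of paired-bootstrap
differences (the same subject resample applied to both sources) and
referred to t(n_subjects − 1).  Cross-checking against coefficient SEs
shows this reproduces the expected order of magnitude for study-scale
effects.

**Sham comparison.** One-way ANOVA over three equal-sized groups: target
at its best phase, distractor at its best phase, sham.

## Circular statistics (`phasemod.circular`)

Angles are degrees at the API, radians internally.  Summary: mean
direction (angle of the mean unit vector), resultant length R, angular
deviation √(2(1−R)).

**Rayleigh test.** Z = nR² with the standard finite-n series correction;
an independent 50,000-draw Monte-Carlo null is implemented as an oracle
and agrees within a few percent at study scale (n = 18).

**Von Mises fit.** ML: μ = circular mean; κ solves A(κ) =
I₁(κ)/I₀(κ) = R by bisection (Brent) on the scaled Bessel ratio, capped at
10⁶ and flagged when R = 1.  Goodness of fit: Watson's one-sample U²
after the probability-integral transform through the fitted CDF, with
Stephens' modified statistic and the asymptotic series p-value.  Because
μ and κ are estimated from the same sample, the p-values lean
conservative; the test suite checks they are never anti-conservative.

**Concentration homogeneity.** The standard three-regime two-sample test:
variance-stabilizing arcsine transform for pooled R̄ < 0.45, arcsinh
transform for 0.45–0.70, and a circular-dispersion variance ratio
referred to F for R̄ > 0.70.  Two-tailed.

**Discretization.** With the study design the angles take only four
values; the continuous-distribution tests (Rayleigh, Watson) are then
approximations.  An optional uniform jitter (±45° would tile the circle)
is available for goodness-of-fit stability and is off by default; its use
is recorded in the output.

## Staircase simulation (`phasemod.staircase`)

The virtual listener has a logistic psychometric function with parameters
`srt_true` (dB SNR of 50% keyword accuracy), `slope` (maximum slope,
probability/dB), and guess/lapse rates clamping the asymptotes.  Five
keywords per sentence are scored binomially.  The adaptive rule: start
uniform in [−3, 0] dB (continuous by default; integer-only behind a
flag); ≤ 2 of 5 keywords correct raises the SNR by 1 dB, otherwise it
drops 1 dB; stop at 7 reversals or 17 trials.  Four runs per listener;
the SRT is the mean over the last three runs of each run's final three
presented SNRs (the default reading of "average of the last three SNR
values during the last three repetitions"; taking each run's final SNR
instead is available as `estimator="final_snr"`).

Because Binomial(5, ½) puts exactly half its mass on {3, 4, 5}, the
1-up/1-down rule on this criterion converges to the 50% keyword point for
any symmetric psychometric function without guess/lapse
(`convergence_snr` verifies this numerically).  Measured bias of the
estimator is below ~0.2 dB for slopes ≥ 0.15/dB; the acceptance run
simulates 100 four-run procedures and requires mean error < 0.5 dB.

## Synthetic data (`phasemod.synthgen`)

The cohort generator emulates the experimental design: 18 subjects; per
subject and condition 26 sentences × 5 keywords = 130 scored keywords
near the 50% operating point; target-envelope stimulation modulating the
per-keyword probability by 3.0 percentage points peaking at 0°,
distractor-envelope stimulation by 1.6 points peaking at 180°, sham flat.
Scoring noise is binomial at the keyword level; subjects receive a
Gaussian offset of their overall level (SD 5 points — the study reports
no subject-level variance component, so this default is a placeholder
exposed in `CohortParams`, chosen to produce between-subject scatter of
the magnitude visible in per-subject score plots).  Per-subject centering
removes the offset exactly, so it does not affect the harmonic fits.

What the generator does *not* emulate: sentence-level correlation of
keyword successes (not estimable from summary statistics; actual response
noise could be over- or under-dispersed relative to binomial),
attention-order effects, learning/fatigue, and any dependence of the
modulation amplitude on SNR.  Passing recovery tests therefore show that
the analysis chain is correct and well calibrated under keyword-binomial
noise — not that real data have this noise structure.

**Statistical power at study scale.** Keyword-binomial noise at 130
keywords gives a per-score SD of 100·√(0.25/130) ≈ 4.4 points and a
pooled-regression coefficient SE of ≈ 0.73 points.  The distractor
modulation (|B2| = 1.6) then sits near z ≈ 2.2, so its FDR-corrected
significance replicates in only about half of simulated cohorts, and the
aligned refits — which retain part of a true, strongly phase-locked
modulation — come out non-significant in only about two-thirds.  A joint
qualitative-pattern replication rate of 80% is not attainable under this
noise model; the corresponding acceptance test documents this and is
expected to fail, while amplitude-CI coverage (≥ 90%) and phase recovery
(median circular error < 30°) pass.  Observed effects of this size in
real data with smaller residual noise are entirely consistent with the
model; the limitation is the power of the synthetic design, not the
estimator.

Surrogate envelopes are 1/f-shaped noise bandpassed to 4–8 Hz, rectified
to non-negativity; pair members come from independent substreams spawned
from the seed (requesting identical member seeds is rejected;
`same_signal=True` gives the r = 1 control).  They emulate the theta-band
modulation content of spoken-sentence envelopes, not their broadband
spectrum or phonetic structure.

## Pipeline and reproducibility (`phasemod.pipeline`)

`run_pipeline` executes centering → OLS/robust fits → FDR →
amplitude/phase → bootstrap comparison → aligned refits → best-phase
circular analysis → amplitude and sham comparisons, and writes
report.json, per-fit TSV tables (estimate, CI, FDR p; F/p/r² footer) and
optional figures.  Every stochastic stage receives a seed derived from
the config seed via SHA-256, so a config hash plus seed fully determines
the report; reruns are byte-identical up to the configured output
directory.  All stage errors abort with a stage-tagged message.

The acceptance script runs this pipeline on one study-scale cohort with
n_boot = 2000 (the r² comparison's p-value is stable to well below the
reporting precision at that size), plus 100 envelope pairs and an
18-listener SRT simulation; total runtime is under a minute on one CPU.

## Known limitations

- The Watson U² p-value is asymptotic and conservative under estimated
  parameters; exact parametric-bootstrap calibration is not implemented.
- The robust fit's inferential statistics (z-tests, CIs) rely on the
  normal approximation; no small-sample correction is applied.
- The concentration-homogeneity test's regime constants are asymptotic;
  behaviour for n < ~10 per sample is untested and such inputs are
  rejected.
- The staircase model scores keywords independently within a sentence;
  real keyword successes within a sentence are correlated.
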