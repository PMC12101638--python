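# Methods

## The analysis unit: one pulse cycle

A bruit recording (10–20 s of mono PCM WAV, ≥8 kHz) contains 15–30
cardiac pulse cycles. All spectral statistics are defined per cycle, so
segmentation comes first. The smoothed amplitude envelope (moving RMS,
20 ms window) is periodic at the pulse rate: envelope peaks are found
with a minimum spacing of 60/max_rate seconds and a prominence of at
least 25% of the envelope maximum, and a cycle onset is placed between
each pair of peaks at the *foot of the rising edge* — the last point
still within 3% of the trough-to-peak swing above the trough minimum.
Segments run onset-to-onset; only complete cycles (those closed by a
following onset) are emitted, and durations outside the physiologic
band (40–140 beats/min by default) are discarded.

Two details deserve justification:

* **Onset = rising-edge foot, not envelope argmin.** The quiet phase
  between beats is a near-flat noise plateau; its literal minimum is
  noise-driven, jitters by tens of milliseconds, and is not stable
  under resampling. The rising edge is steep and well-localized. Since
  TMP measures time *from cycle start*, the onset convention directly
  shifts TMP; anchoring to the rising edge keeps the recovered TMP of
  generated cycles within about one point of the generating value. The
  3% threshold sits well above the plateau's noise ripple but low
  enough on the edge to capture the true acoustic start.
* **Unmodulated input must fail loudly.** Stationary noise has an
  envelope that never drops below ~70% of its maximum, while a
  pulsatile bruit falls close to silence between beats. Detection
  therefore requires the envelope to dip below 50% of its peak
  somewhere; otherwise a no-cycles error is raised rather than
  returning spurious segments. All thresholds are relative to the
  envelope's own level, so segmentation is invariant to amplitude
  scaling.

Per recording, the three (configurable) cleanest cycles are analysed,
scored by envelope peak-to-trough ratio. Segments containing clipped
samples are demoted regardless of their ratio — clipping inflates the
envelope peak, so a pure ratio score would otherwise *prefer* corrupted
cycles.

## Band-power statistics

The short-time spectrum uses a 50 ms Hann window at 75% overlap: 20 Hz
frequency resolution (five bins per 100-Hz band) and ~60–80 frames per
cycle. Per-Hz power densities are integrated into forty contiguous
bands, band f covering [f−50, f+50) Hz, f = 100 … 4,000, and expressed
as density over the nominal 100-Hz bandwidth. PSD is kept in linear
per-Hz units throughout: the PSD200 subtraction is only meaningful on a
linear scale.

* **Time normalization.** Each cycle's frame axis is resampled to
  exactly 100 bins by zero-order-hold sampling at bin centers, then
  rescaled per band so mean level (hence integrated power) is conserved
  exactly. Sampling rather than mean-pooling is deliberate: averaging
  across frame boundaries dilutes narrow power peaks and can hand the
  argmax to a near-tied competitor elsewhere in the cycle, whereas
  sampling preserves the argmax location exactly whenever the cycle has
  at most 100 frames (always true for cycles under 1.25 s at the
  default hop). This is verified against a brute-force argmax oracle on
  the raw frame axis.
* **TMP** = argmax bin + 0.5 (bin center, in percent of the cycle),
  ties to the earliest bin; a band with no power has no maximum and is
  reported missing. TMP is invariant to amplitude scaling and uniform
  time stretching by construction.
* **Whole-cycle band PSD** uses Welch's averaged periodogram with the
  same window, aggregated to the same bands; the Parseval check (band
  integrals vs in-band variance) holds within 5%.
* **MF** is the band center of the maximal whole-cycle PSD, ties to
  the lowest frequency. **PSD200** = 2·P(200) − P(100) − P(300).
* **Subject aggregation**: arithmetic mean of TMP, band PSD and PSD200
  over the selected cycles; MF is the modal band (ties low). The mean
  is chosen for simplicity and unbiasedness; no robustness weighting is
  attempted at three cycles per subject.

## The TMP model

Per subject and band over 100–700 Hz (the range in which TMP falls
before flattening), observations enter a Gaussian GLM with log link on
the TMP *fraction* (tmp/100):

E[TMP] = exp(β₀ + β_Hz·Hz + β_DM·DM + β_HT·HT + β_Event·Event + β_V·Vintage)

Vintage is dichotomized at five years (inclusive). "log(TMP)" is read
as the link function, not a pre-transform of the response: only that
reading reproduces the published prediction grid from the published
coefficients (e.g. exp(−1.4819 − 0.0003·200 − 0.1709) = 0.180 → 18.0%).
The full model (A) carries all four history indicators; the reduced
model (B) keeps Hz, diabetes and vintage. Models are compared by the
standard lower-is-better AIC rule. Wald standard errors, normal-quantile
CIs and delta-method CIs on the exponentiated linear predictor are
used for the prediction grid; the grid is produced for the four
diabetes × vintage groups at 100–700 Hz.

**Coefficient coding.** The reference coefficient set (the reduced
model's published values: intercept −1.4819, Hz −0.0003, diabetes
−0.1709, vintage +0.1324) reproduces the published grid only when the
diabetes coefficient is applied to the *no*-diabetes group. The package
defaults to that grid-consistent coding (`coding="table4"`) and exposes
the declared coding (`coding="as_stated"`, coefficient on the diabetes
indicator itself) everywhere the choice matters. Under the default
coding, diabetes and longer vintage both *raise* expected TMP — a later
power peak, consistent with the arteriosclerosis interpretation.

**Independence simplification.** The seven per-band rows of one subject
are treated as independent observations, as the published standard
errors imply. This understates uncertainty to the extent that bands
are correlated within a subject; a mixed-effects or GEE extension is
deliberately out of scope.

PSD200 group differences (diabetes, hypertension, event, vintage) use
Welch's unequal-variance t-test, two-sided, α = 0.05, no multiplicity
correction across the four comparisons. Per-group 95% CIs are t-based
(mean ± t₀.₉₇₅,ₙ₋₁·sd/√n). The risk flag is strict: PSD200 < threshold,
default 14,246 — the upper CI bound of the event group's mean in the
reference cohort. Absolute PSD units depend on recorder gain, so the
threshold must be recalibrated per recording setup; the default is
meaningful only for data on the reference scale.

## The synthetic-data generator

The generator emulates the study conditions so the pipeline can be
exercised and validated without patient recordings.

* **Cohort**: 53 subjects by default, with covariate prevalences fixed
  at the reference cohort's mix (diabetes 54.7%, hypertension 67.9%,
  AVF-related event 17.0%, vintage ≥5 y 58.5%). Indicators are
  independent Bernoulli draws. Vintage in years is exponential with
  rate chosen so P(vintage ≥ 5) matches its prevalence — the simplest
  non-negative distribution consistent with the published five-year
  split, given that only a mean ± sd (6.9 ± 7.4 y) is otherwise known.
* **Waveform**: each cycle is Gaussian noise shaped in the frequency
  domain by a target power spectrum — a low-frequency plateau rolling
  off above ~800 Hz (sixth-order, knee at 750 Hz, matching the
  published spectral profile of a functioning access concentrated
  below ~450 Hz) plus a Gaussian bump at 200 Hz (sd 45 Hz, narrow
  enough to stay inside one band) scaled by `peak_prominence`
  (default 2.0, which yields MF = 200 Hz in ≳97% of cycles and a
  clearly positive PSD200). The shaped noise is multiplied by a
  gamma-shaped temporal envelope (shape 3) whose mode sits at
  `tmp_target` percent of the cycle — by default the model-implied TMP
  for the subject's covariates at 200 Hz, so cohort-level acoustic and
  regression ground truths agree. Shape 3 is a compromise measured in
  the closed loop: a sharper peak (higher shape) lengthens the silent
  onset phase, which destabilizes trough placement and biases recovered
  TMP late, while shape 3 keeps the envelope above the noise floor
  through the cycle and recovers the target within about one point.
* **Event subjects** have the 200-Hz bump multiplied by 0.25,
  reproducing the collapsed 200-Hz prominence observed in subjects who
  went on to surgical intervention — attenuation rather than added
  high-frequency content, as the published group spectra show a peak
  collapse, not a shift.
* Cycle durations are Normal(0.8 s, 0.05 s) clipped to [0.3, 2] s
  (75 bpm nominal); the waveform peak is normalized to 0.9 and a white
  noise floor is added at −50 dB relative to peak (a quiet clinical
  room). Everything is a pure function of the seed; dataset generation
  derives one child seed per subject and records it in the manifest.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: stethoscope and room transfer
functions, respiration and motion artifacts, arrhythmia (cycle
durations are i.i.d.), the high-frequency components reported for
stenotic accesses, any dependence of the spectrum on diabetes,
hypertension or vintage (only the event effect and the TMP timing are
covariate-linked), and absolute PSD scale. Closed-loop results validate
the *pipeline's* correctness, not clinical performance.

## Numerical conventions and scaled-down study sizes

* GLM fitting: IRLS (statsmodels), up to 200 iterations, tolerance
  1e−10; a numerically perfect fit (zero deviance) is accepted even
  when the relative convergence flag fails. Constant covariates and
  unmatched subject ids are hard errors.
* Monte-Carlo checks in the test suite use enough replicates for their
  assertions (60 cohorts for unbiasedness/coverage in the unit test,
  200 in the acceptance battery; 12 generated cohorts for the Welch
  power check; 300 permutations for null calibration), keeping the full
  suite under half a minute of compute for the deterministic parts and
  a few minutes overall.
* WAV I/O is PCM 16-bit with symmetric scaling by 32767, giving an
  exact write/read round trip up to one quantization step; out-of-range
  samples are an error, never silently clipped. Multi-channel input is
  down-mixed by channel mean (logged).
* Displayed percentages use decimal half-up rounding to one decimal.

## Known limitations

* The onset convention (rising-edge foot) is a repository decision; the
  source procedure was manual and auditory. TMP values shift with the
  convention, so comparisons across implementations need care.
* Within-subject correlation across bands is ignored (see above).
* The PSD200 risk threshold is gain-dependent and not transferable
  across recording hardware without recalibration.
* Welch tests on an n=9 event group have limited power and normality
  robustness; the package reports them as the reference analysis did.
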