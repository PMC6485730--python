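# Methods

## Scope and data model

The pipeline analyzes evoked and spontaneous whisker movements of the mouse
whisker pad after facial nerve transection, plus a downstream comparison of
transcript-level differential-expression (DE) tables between two denervated
muscles. The atomic kinematic input is one trial's whisker angle sampled at
500 frames/s (2-ms sample period), in degrees with protraction positive,
annotated with subject, day relative to lesion (negative = prelesion; a
real number so sub-day timepoints such as +6 h = 0.25 fit), stimulus
duration and stimulus onset. Stimulus onset is an explicit column of the
trace CSV rather than inferred, because trial records are 3 s long and the
onset is a free protocol choice. Missing frames (tracking artifacts) are
masked samples; downstream operations interpolate masked runs of at most 5
samples linearly and reject trials with longer gaps.

The stimulus protocol mirrors the study design: eight replicates each of
1, 3, 5, 10, 20, 50, 100 and 1,000-ms light stimuli per subject and day.

## Kinematic metrics

All metrics are measured relative to a baseline angle, the mean over the
200 ms preceding stimulus onset (the reference angle is otherwise
undefined for head-fixed whisker data). The response search window is
stimulus onset to onset + 2,000 ms, wide enough to include post-offset
peaks of brief stimuli.

* **Peak amplitude** (deg): maximum baseline-subtracted angle in the
  window, on the raw (unsmoothed) trace.
* **Peak velocity** (deg/s): maximum of the first derivative of the
  Savitzky–Golay-smoothed trace. Defaults: window 11 samples (22 ms),
  polynomial order 3 — wide enough to suppress frame noise while
  preserving a ~16-ms twitch rise. The derivative uses central differences
  in the interior and one-sided differences at the edges. Derivative of
  the smoothed trace (rather than a smoothed derivative) is used; the two
  are indistinguishable for these signals.
* **Time-to-peak** (ms): time of the amplitude maximum minus onset.
* **Half-width** (ms): full width at half maximum, with the two
  half-maximum crossings flanking the peak located by linear
  interpolation; flagged censored when the response has not decayed below
  half maximum by the end of the record.
* **Persistence index** (PI, unitless): for the 1,000-ms stimulus only,
  the response amplitude at stimulus offset — operationalized as the mean
  over the final 10 ms of the stimulus — divided by peak amplitude,
  clamped to [0, 1]. Higher PI means less fatigable.

A trace whose peak does not exceed 3× the baseline standard deviation is
flagged "no response" and its time metrics are null, which keeps argmax
statistics off pure noise. Group-level responder counts instead use the
absolute 1° response criterion (the same default as the sensitivity
threshold): a maximum over ~1,250 window samples of pure noise reaches
~3.2 standard deviations on average, so a 3σ cut is a near-coin-flip on
non-responders, while the absolute criterion separates genuine responses
from the noise floor by more than an order of magnitude at realistic noise
levels.

Replicates are averaged within subject **before** metric extraction
(matching how example traces are presented as averages of repeated
responses), with per-replicate metrics retained for dispersion; subject
values are then summarized across subjects as mean ± SE (sample sd / √n;
SE for n = 1 is reported as 0 and flagged). Duration–response families
report one row per protocol duration; the sensitivity threshold is the
smallest protocol duration whose mean peak amplitude reaches an absolute
criterion (default 1°, configurable to 3× baseline sd).

Retractions (negative-going responses) are analyzed by the same extractor
with a sign flip (`response_sign = -1`); there is no retraction-specific
logic.

## Fasciculation spectra

Spectra are computed only on stimulus-free records of at least 1 s
(evoked movements would contaminate the 5–8 Hz band). The record is
linearly detrended and a single rectangular-window periodogram is taken,
normalized so that the **sum of power over bins equals the variance of the
detrended signal** (a Parseval identity the validation stage asserts at
1e-9 relative). "5–8 Hz power" is the *mean* power over the bins inside
the closed band, tagged as such in the outputs; whether published band
values are bin means or band sums is not determinable, and the mean makes
values comparable across record lengths. Band power is in deg² since the
signal is an angle. Peak-to-peak amplitude is max − min, or the 99th − 1st
percentile in robust mode (preferred on noisy data). Time courses average
band power within and then between subjects, per condition label
(e.g. vehicle vs. RyR1-antagonist).

## Synthetic generators

The generators exist so every stage is testable with planted truth; they
are first-class, tested code.

**Evoked twitch.** No generative waveform model is implied by whisker
data themselves, so the model is chosen to control the four phenotype axes
of denervation independently:

```
r(u) = A(d) · (1 − e^(−u/τ_rise)) · (p + (1 − p) e^(−u/τ_fatigue)),  0 ≤ u ≤ d
A(d) = A_max · d^h / (d^h + d50^h)
```

with `u` the time since onset + latency, exponential decay with `τ_decay`
after the drive ends, and i.i.d. Gaussian frame noise. Sensitivity is set
by `d50` (Hill midpoint, ms), speed by `τ_rise` (the initial slope, hence
peak velocity, is `A/τ_rise`), amplitude by `A_max`, fatigability by the
plateau fraction `p` — which is the ground truth the persistence index
estimates. Calibrated primitives support tests where a metric's truth must
be set exactly: `target_peak_deg` rescales the waveform so its noise-free
maximum on a 0.1-ms grid equals the target; a latency calibration places
the dense-grid peak at an exact time-to-peak; and a Gaussian bump
`peak·exp(−4 ln2 (t−t_peak)²/FWHM²)` provides an exact analytic FWHM and
peak velocity (`peak·√(2k)e^(−1/2)`, `k = 4 ln2/FWHM²`).

**Fasciculations.** Pure-tone mode is `(p2p/2)·sin(2π f0 t + φ)` with
optional Wiener phase jitter — exact peak-to-peak on the continuous
waveform (discretization at 500 frames/s undershoots by < 0.1%).
Narrowband mode band-limits white Gaussian noise to 5–8 Hz by FFT masking
and rescales so the 1st–99th percentile range equals the requested
peak-to-peak value.

**Cohorts.** Subject-level parameters deviate multiplicatively from the
day means: log-normal with CV 0.3 by default on amplitude-like parameters,
truncated-normal on time constants and latency, and truncated-normal with
CV 0.1 on the plateau fraction — a bounded ratio near 0.77 post-lesion
would mass-clip at 1 under CV 0.3 and bias the group mean. Per-trace seeds
derive deterministically from the master seed (`numpy` SeedSequence), so a
cohort is reproducible and per-trace streams are independent.

**DE tables.** Two tissue tables with explicit planted significant sets
|A|, |B| and |A∩B| (shared transcripts get concordant signs, matching the
observed absence of opposite-direction regulation). Truly regulated
transcripts receive Wald q-values well below the significance threshold,
an LRT flag, and |log2 FC| ≥ 1; null transcripts get uniform q-values,
N(0, 0.3) log fold changes and an α-rate LRT flag, so false positives
through the full filter chain are bounded by α (and are in practice
~10⁻⁶ per transcript). TPM columns per tissue/day/arm are log-normal with
the fold change applied to the injured arm, growing over days.

### What the generators do not emulate

Real whisker traces contain slow postural drift, correlated (non-white)
tracking noise, whisking bouts, and occasional gross artifacts; real DE
tables have correlated q-values, fold-change-dependent dispersion and
missing transcripts. Passing tests therefore demonstrate the estimators'
correctness and calibration on the assumed signal + white noise model, not
robustness to every failure mode of tracking or sequencing.

## Demo study and presets

`run_demo` simulates the full design: a 6-subject nerve cohort (baseline,
+0.5 h, +6 h, +24 h) and a 9-subject muscle cohort (baseline and days
1–10), 8 durations × 8 replicates, ~7,900 traces, in a few seconds on one
CPU. Presets are calibrated so the *measured* noise-free group-mean
metrics equal published group means, inverting the measurement where the
estimator is biased relative to the raw parameter:

* the 1,000-ms peak amplitude is calibrated via the dense-grid envelope
  maximum (13.88° at baseline → 20.32° at day 7);
* the plateau fraction is calibrated by root-finding so the measured PI of
  the noise-free waveform equals the target (0.3012 → 0.7655), since the
  measured PI exceeds `p` whenever fatigue has not settled by offset;
* nerve presets are an all-or-none brief twitch (tiny `d50`, steep Hill,
  near-zero plateau) calibrated to an 8.77° peak, scaled ×1 at +0.5 h,
  ×0.8 at +6 h and ×0 at +24 h. The multiplicative rise×fatigue×decay
  model cannot simultaneously match the published nerve amplitude,
  velocity and 13.8-ms half-width (the real twitch is Gaussian-like);
  amplitude, the quantity the responder check uses, is matched and the
  others are qualitative.

Enhancement ramps linearly between day 1 and day 3 and holds, and
fasciculation amplitude rises from day 2 to saturate at 2.45° peak-to-peak
— so the demo reproduces the qualitative findings (responses abolished at
24 h for 6/6 nerve subjects; amplitude, velocity and PI elevated from day
2; PI at day 7 near 254% of baseline) without asserting any group-level
statistic the pipeline does not itself compute. `validate` re-reads a
run's outputs and checks the machine-verifiable invariants: Parseval,
PI ∈ [0, 1], Venn identity, filter monotonicity, finite z-matrix.

## DE comparison conventions

* "Fold change of at least 2" is |log2 FC| ≥ 1, boundary inclusive, in
  either direction. The Wald q-value threshold defaults to 0.05
  (configurable); LRT membership is required by default.
* z-scores of normalized TPM use the sample standard deviation (ddof = 1)
  across the included condition columns (whisker days 1/3/7 and soleus
  day 3 injured arms by default); a within-day mode is available by
  passing the per-day column subset. Constant rows get z = 0 and a
  degenerate flag.
* "Polar expression" keeps transcripts significant in ≥ 1 dataset whose
  day-3 values have strictly opposite signs; zero is not polar. The signed
  value defaults to the day-3 z-scores, with log2 FC signs as an
  alternative mode.
* Gene-family labels for heatmap tables are a user-supplied mapping; no GO
  enrichment is computed. Heatmap rows order by group, then descending |z|
  at the reference condition, then id — deterministic across runs.

## Numerical choices and edge cases

* Savitzky–Golay smoothing is exact on polynomials up to the fit order, so
  linear ramps differentiate exactly; a 5-Hz sinusoid's peak velocity is
  recovered within 0.03%.
* A slope discontinuity (an instantaneous-onset exponential rise) is the
  one waveform whose peak velocity the smoothed estimator systematically
  underestimates (~23% at the default window): the maximum slope lives at
  the kink that smoothing exists to round off. Velocity ground-truth tests
  therefore use the smooth Gaussian primitive, whose analytic peak
  velocity is recovered within 0.6% for FWHM ≥ 50 ms.
* Peak amplitude is taken on the raw trace (no smoothing bias); on
  noise 0.2° with 8-replicate averages it is recovered within 2% for
  fatiguing responses. Flat-top responses (p = 1) are the worst case for
  the max estimator — ~500 near-peak samples yield a +2–2.6% max-of-noise
  bias — documented here rather than hidden by smoothing, which would
  corrupt sharp noiseless peaks instead.
* The persistence index estimates the plateau fraction within 0.05 (at
  noise ≤ 0.2°, 8 replicates) when the plateau is identifiable within the
  stimulus: τ_rise ≪ τ_fatigue and τ_fatigue well below the 1,000-ms
  stimulus. Outside that regime the measured PI is a property of the
  waveform, not a biased estimate of `p` (the demo presets invert this
  mapping explicitly).
* Periodogram bins are spaced 1/T Hz; a tone is recovered within one bin,
  and off-bin tones leak ~4% of their power outside a 3-Hz band with a
  3-s rectangular window (tests use on-bin record lengths where exact
  capture is asserted).
* Ties in the amplitude argmax resolve to the earliest sample. Baseline
  windows with no usable samples, stimuli extending past the trial,
  empty frequency bands, single-column z-score input, and infeasible
  planted overlaps all raise validation errors naming the problem.

## Limitations

Mixed-model/ANOVA inference, post hoc testing, GO enrichment, read
processing and DE model fitting are out of scope; the pipeline consumes DE
tables and reports descriptive summaries only. The published per-tissue DE
counts cannot be reconciled exactly with the published union/intersection
(the day-3 whisker subset size is unreported), so the comparison stage
treats overlap structure as data rather than deriving one count from the
other. Half-width can be measured on single trials or replicate averages;
averages are the default and the two differ on noisy data.
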