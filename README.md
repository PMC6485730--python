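# whiskerkin

Analysis pipeline for the functional and transcriptomic state of denervated
whisker pad muscle. After facial nerve transection in the mouse, the
paralyzed whisker pad can still be driven directly with optogenetic muscle
stimulation (ChR2), and — unlike most skeletal muscle — it *gains* function:
evoked whisker protractions become larger, faster, more sensitive to brief
stimuli, and less fatigable, while the denervated fibers fasciculate
spontaneously at 5–8 Hz. `whiskerkin` implements the quantitative pipeline
behind that kind of study for physiologists working with high-speed
(500 frames/s) whisker tracking and bulk RNA-seq:

* **kinematics** — per-response metrics from whisker-angle time series:
  peak amplitude, peak velocity (peak of the first derivative after
  Savitzky–Golay smoothing), time-to-peak, half-width (FWHM), and the
  persistence index PI = (amplitude at the end of a 1,000-ms stimulus) /
  (peak amplitude), a fatigability statistic in [0, 1]; stimulus
  duration–response families and sensitivity thresholds; within- then
  between-subject averaging with mean ± SE summaries.
* **fasciculation** — variance-normalized periodograms of stimulus-free
  records (Parseval: bin powers sum to the signal variance), mean 5–8 Hz
  band power, peak-to-peak amplitude, and day-by-day / treatment summaries.
* **decompare** — post-DE transcriptome comparison: the LRT ∩ Wald ∩
  (fold change ≥ 2) filter chain, Venn overlap between tissues,
  opposite-direction counts, per-transcript z-scores of normalized TPM,
  and the polar-expression filter (opposite day-3 signs between tissues).
* **synthetic_data** — generators for all of the above with planted ground
  truth: a Hill-saturating twitch model
  `r(u) = A(d)·(1−e^(−u/τ_rise))·(p+(1−p)e^(−u/τ_fatigue))` with
  `A(d) = A_max d^h/(d^h+d50^h)`, pure-tone and narrowband fasciculation
  records, cohort simulation with between-subject variability, and
  two-tissue DE tables with exact planted overlap structure.

Real inputs are a long-format trace CSV
(`subject,day,trial,stim_duration_ms,stim_onset_ms,time_ms,angle_deg`) and
transcript-level DE TSVs; no raw video or sequencing data are required.

## Worked example

```python
from whiskerkin import (TwitchParams, simulate_twitch, extract_metrics,
                        percent_of_baseline)

# a noise-free nerve-type twitch calibrated to an 8.77-degree peak
params = TwitchParams(tau_rise_ms=5, tau_decay_ms=15, plateau_fraction=1.0,
                      latency_ms=5, noise_sd_deg=0.0, target_peak_deg=8.77)
trace = simulate_twitch(params, stim_duration_ms=5, stim_onset_ms=500)
m = extract_metrics(trace)
print(f"peak {m.peak_amplitude_deg:.2f} deg, time-to-peak {m.time_to_peak_ms:.1f} ms")
print(f"PI percent of baseline: {percent_of_baseline(0.7655, 0.3012):.0f}%")
```

prints

```
peak 8.77 deg, time-to-peak 10.0 ms
PI percent of baseline: 254%
```

The measured peak equals the calibration target exactly, the peak falls at
latency + stimulus duration, and a persistence index rising from 0.3012 to
0.7655 is a 254% change from baseline.

The full demo study — a 6-subject nerve cohort whose evoked responses are
abolished 24 h post-lesion, a 9-subject muscle cohort with enhancement from
day 2, fasciculation time courses, and a two-tissue DE comparison with 63 of
692 regulated transcripts in common — runs from the command line:

```sh
whiskerkin demo --seed 1 --out demo_out
whiskerkin validate --dir demo_out
```

`validate` re-checks every pipeline invariant (Parseval identity, PI range,
Venn identity, filter monotonicity) over the run's outputs. Subcommands
`simulate`, `kinematics`, `fasciculation` and `decompare` expose the
individual stages.

## Documentation

`docs/methods.md` describes the generative models, estimator conventions,
calibration procedures, numerical choices and known limitations.
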