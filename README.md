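# wormsleep

Quantification pipeline for *C. elegans* sleep-circuit imaging.  Long
time-lapse recordings of single larvae (fluorescence of identified neurons
such as the sleep-active interneuron RIS, tracked landmark positions,
pharyngeal pumping status) and short optogenetic stimulation trials are
turned into the measurements sleep-circuit studies report: ΔF/F and ΔR/R
activity traces, locomotion speed and movement direction, sleep-bout
structure through lethargus, calcium-transient statistics, and
stimulation-trial effects including post-inhibition rebound dynamics.

It is written for experimentalists analyzing chamber-based worm imaging who
want the whole quantification stack — extraction to statistics — as tested,
scriptable, provenance-tracking code, plus a seeded synthetic-recording
generator that plants ground truth so every stage can be validated without
any raw data.

## What it computes

- **ROI traces**: inside a square ROI following the tracked neuron, the top
  fraction of pixels by intensity is signal, the rest background;
  `F = mean(signal) − mean(background)`.  Normalizations
  `ΔF/F = (F − F0)/F0` and ratiometric `ΔR/R` (GCaMP over a
  calcium-insensitive channel) are exactly gain-invariant.
- **Behavior**: speed from landmark displacement (μm/s); forward/reverse
  calls from nose–pharynx geometry with a 2 μm/s sleeping override;
  lethargus as the longest sustained non-pumping phase.
- **Sleep bouts**: speed is smoothed (local linear regression over 20
  samples, or robust local quadratic over 3%/40 samples), min–max
  normalized over the analyzed span, and runs below a 10% (or 5%) threshold
  lasting ≥ 2 min become sleep bouts; short stimulation trials use the
  mean-wake-speed immobility proxy instead (5–30% thresholds).
- **Calcium events**: peaks by topographic prominence (wide: span 60,
  prominence 0.15; narrow: span 5, prominence 0.2), event-triggered
  ensembles with NaN-aware mean ± SEM, percentile-exclusion baselines, and
  transient counting at ≥ 2× baseline.
- **Trials**: baseline/stimulation/recovery windows around each stimulation
  epoch; exact Wilcoxon signed-rank for paired window means; Fisher's exact
  test for pooled sleep fractions; Shapiro-gated Welch/Kolmogorov–Smirnov
  for group comparisons; activating/inhibiting/nonresponsive and
  mobilizing/nonmobilizing classification; rebound latency and peak;
  dose-response fits `y = a(1 − e^{−bx})` (BoxLucas1), `y = c − a·bˣ`
  (asymptotic), and the logistic `y = A2 + (A1 − A2)/(1 + (x/x0)^p)`.

See `docs/methods.md` for models, parameter defaults, and numerical
conventions.

## Worked example

```python
from wormsleep import (SyntheticConfig, SmoothingConfig, generate_recording,
                       compute_speed, compute_dff, detect_lethargus,
                       detect_sleep_bouts, bout_statistics, detect_peaks)

cfg = SyntheticConfig(seed=7, duration_s=5400.0, lethargus=(600.0, 4200.0),
                      bout_distribution="fixed", sleep_bout_mean_s=600.0,
                      motion_bout_mean_s=600.0)
rec, truth = generate_recording(cfg)          # 90-min worm, 5-s sampling

leth = detect_lethargus(rec.pumping_track())  # Interval(600.0, 4200.0)
speed = compute_speed(rec.landmark_track())
bouts = detect_sleep_bouts(speed, SmoothingConfig("local_linear", 20),
                           threshold_fraction=0.10, min_duration_s=120.0,
                           span=leth)
print(bout_statistics(bouts, leth))
# {'sleep_fraction': 0.469, 'bout_frequency_per_h': 3.0,
#  'mean_bout_duration_s': 563.3, ..., 'n_bouts': 3}

dff = compute_dff(rec.trace("RIS"), (0.0, 540.0))
peaks = detect_peaks(dff, smooth_span=60, min_prominence=0.15)
print(peaks.peak_times)                       # [1235. 2435. 3630.]
```

The worm was built with three 10-min sleep bouts (planted sleep fraction
0.50; the detected 0.469 reflects smoothing at the bout edges) and one
RIS-like calcium transient at each sleep-bout onset (planted at 1200, 2400,
3600 s; the detected peak times sit at the transient maxima, ~35 s after
onset for the 3 s/30 s rise/decay kinetics).

A CLI wraps the same stages:

```bash
wormsleep simulate --out worm.csv --seed 7
wormsleep run worm.csv --out results/
wormsleep bouts worm.csv --out results/  # bout stats as JSON
```

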