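# Methods

`wormsleep` quantifies *C. elegans* sleep-circuit recordings: long time-lapse
movies of single worms in microchambers (fluorescence of identified neurons
plus tracked landmark positions, sampled every 3–10 s for minutes to hours)
and short optogenetic stimulation trials.  This note documents the models,
parameters, numerical choices, and the limits of what the synthetic
benchmark demonstrates.

## Signal extraction and normalization

An ROI is a square of side `2·half_size + 1` pixels centered on the tracked
landmark, clipped at frame edges.  Inside the (clipped) ROI, the top
`signal_fraction` of pixels by intensity are signal and the remainder is
background; the reported value is `mean(signal) − mean(background)`.  Ties
at the partition boundary break by row-major pixel index, making the result
deterministic.  `signal_fraction` defaults to 0.10 and is recorded in trace
provenance; the appropriate fraction depends on neuron size relative to the
ROI and should be configured per preparation.  Head-region "pan-neuronal"
measurements use the same operation with a large ROI — there is no separate
code path.

ΔF/F is `(F − F0)/F0` with `F0` the mean of a baseline window, a boolean
mask (e.g. all wake samples, for recordings spanning wake and lethargus), or
each trial's own baseline phase.  It is exactly invariant under any
multiplicative gain of F.  ΔR/R divides the calcium channel by a
calcium-insensitive reference channel before the same normalization, which
cancels any gain applied to both channels (bleaching, focus, illumination).
When the two channels are acquired interleaved, the reference is matched to
the calcium time base by nearest-neighbor lookup; a nearest sample more than
one calcium sampling interval away is an error rather than silently
interpolated.

## Locomotion and behavioral state

Speed is the frame-to-frame displacement of the tracked landmark divided by
the frame interval (μm/s); the first sample repeats the second so every
derived trace keeps the recording length.  The same convention applies to
the image-difference activity proxy (mean absolute pixel difference per
pixel), used when no fluorescent landmark exists.  Manual-tracking stage
motion is undone by subtracting the displacement of a recorded stage corner.

Movement direction uses two head landmarks: for consecutive frames, if the
nose of frame i+1 is farther from the pharynx of frame i than the nose of
frame i was, the worm advanced; nearer means reversal; an exact tie is
undetermined.  Pairs whose tracked-point speed falls below 2 μm/s are scored
sleeping regardless of geometry.  The pairwise rule is valid only while the
per-frame displacement is smaller than about twice the nose–pharynx
distance; at larger steps a reversal can masquerade as forward motion.  An
optional 3-frame majority vote (off by default) suppresses single-frame
label jitter.

Lethargus is annotated as the longest contiguous non-pumping run of at least
20 min (pharyngeal pumping stops through lethargus; the minimum duration
excludes brief pump pauses — the value is a package default, configurable).

## Smoothing

Three local-regression smoothers share one engine: a centered window
(truncated, not shifted, at record edges), tricube distance weights, and a
weighted polynomial fit evaluated at the window center.

* `moving_average` — plain centered mean.
* `local_linear` — degree 1; the long-recording speed smoother (span 20
  samples).
* `robust_local_quadratic` — degree 2 with iterated robustness: after each
  global pass, residuals are turned into bisquare weights and samples whose
  absolute residual exceeds `robust_cutoff` (default 6) times the mean
  absolute deviation of the residuals get zero weight; at most 5 passes.
  Spans are given either as counts (e.g. 40) or fractions (3% of the trace).

Even spans widen to the next odd count so windows stay centered; fractional
spans resolve as `max(3, round(frac·n))`, again forced odd.  If robustness
zeroes so many weights that the polynomial is underdetermined, the engine
falls back to the weighted mean of the window.  The "6 mean absolute
deviations" cutoff is an interpretation of an ambiguous description of the
original toolbox's robust weighting; the unit test pins the behavior against
an independent plain-loop reference, and the degree-1 non-robust variant is
cross-checked against `statsmodels` lowess on a uniform grid.

## Sleep-bout segmentation

For long recordings: smooth the speed trace, min–max normalize it over the
analyzed span only (so the result is exactly invariant under rescaling of
the speed), and score every contiguous run of normalized speed strictly
below a threshold fraction lasting at least a minimum duration as a sleep
bout.  Defaults are 10% and 2 min, with a 5% variant in the preset registry.
Motion bouts are the complement of sleep within the span, so sleep + motion
time always equals the span exactly.  The analyzed span (typically the
lethargus interval, or 2 h before lethargus through its end) is an explicit
input, never inferred.  A smoothed trace with no dynamic range makes
normalization undefined and is an error.

Threshold comparison is strict `<` (boundary equality is not quiescent);
the duration rule is inclusive `≥`.  Window lengths in minutes floor to
sample counts.  Boundary accuracy is limited by the smoothing span: a
square-wave bout's detected edges move inward by roughly 10–20% of the span,
so bouts barely above the minimum duration can be shortened below it.  The
planted-truth benchmark therefore scores boundaries with a tolerance of one
smoothing span.

Short stimulation trials cannot carry a minimum-duration rule; there a
sample is quiescent iff its speed is strictly below a configured fraction
(5–30%, default 10%) of that worm's mean wake speed, with the wake window
given explicitly (the trial baseline in practice).

## Calcium peaks, alignment, and baselines

Transients are local maxima (plateaus report their leftmost sample) of the
smoothed trace scored by topographic prominence: the peak height above the
higher of the two lowest saddles separating it from strictly higher terrain.
Record edges are treated as dropping to −∞, and a peak with no higher
terrain on either side (the global maximum) gets its height above the global
minimum.  This edge convention differs from the common toolbox default
(height above the higher of the two side minima) for the highest peak only;
it is pinned by an O(n²) brute-force saddle-search oracle in the tests.
Width classes are parameter presets: wide = span 60 / prominence 0.15,
narrow = span 5 / prominence 0.2, co-imaging = span 30 / prominence 0.2, all
in trace (ΔF/F) units.  Peak count is monotonically nonincreasing in the
prominence threshold.

Event alignment cuts fixed windows around event times (peaks or bout
onsets) into a lag matrix; lags outside the record are NaN, never zero, and
per-lag mean ± SEM use only available rows.  Rows are optionally
re-normalized as ΔF/F against the mean of a fixed number of samples (10 for
bout-onset alignment) immediately preceding the event; events with no
available baseline are dropped with a warning.

Activity baselines for transient counting exclude a top percentile band of
the trace (95–100 for low-transient traces, 75–100 for high-transient
mutants; linear-interpolation quantile convention, samples strictly above
the lower percentile value), bridge the gaps by linear interpolation (edge
values extend), and smooth with the robust quadratic smoother at 3% span.
A transient is a maximal run where the trace is at least `factor` (default
2, inclusive) times the baseline.

## Trial analysis

A stimulation trial is cut from each epoch of the stimulation mask, with
baseline/stimulation/recovery windows as offsets relative to stimulation
onset (the shipped preset uses −60…−3 s / 0…57 s / 60…117 s, plus a
short-baseline and a blue-light variant).  ΔF/F is normalized per trial to
its own baseline window.  Trials whose baseline or stimulation window is
not covered by the recording are dropped with a warning.

* **Paired comparisons** (same worms, two windows) use the two-sided
  Wilcoxon signed-rank test: zero differences dropped, midranks for ties,
  exact null distribution by generating-function convolution for n ≤ 25,
  normal approximation with continuity and tie corrections above.
* **Sleep fractions** pool quiescent/mobile frame counts over trials into a
  2×2 table tested by Fisher's exact test.  Frames, not trials, are the
  counting unit, matching the sleep-fraction semantics; this choice is a
  package decision.
* **Between-group comparisons** gate on Shapiro–Wilk normality of both
  samples at α = 0.05: Welch's t if both pass, two-sample
  Kolmogorov–Smirnov otherwise (constant samples route to KS).

Response classification formalizes what was originally a visual call:
Δ = mean(stim) − mean(baseline) against k·SD(baseline), k = 2 by default,
recorded in every output.  Mobilization: a trial is nonmobilizing iff any
quiescent sample occurs within 180 s after stimulation end, n/a if the
recording truncates that window.  Rebound transients after inhibition:
onset is the first time at or after stimulation end (the search includes
the last stimulation sample; latency clamps at 0) where ΔF/F exceeds
mean(baseline) + k·SD(baseline) for at least 2 consecutive samples; the
peak maximum is taken between onset and the first return below threshold;
absence is a value (non-responder), not an error.  Latency is nonincreasing
as k decreases.  With ~11 baseline samples the SD estimate is noisy and
Gaussian noise crosses a 2-SD threshold for 2 consecutive samples in a few
percent of trials; the synthetic benchmark therefore quantifies recovery at
k = 3, which sits above the noise floor of its configured noise level while
leaving every planted rebound (amplitude ≥ 0.5 ΔF/F) unambiguous.

Dose-response fits: `box_lucas_1` `y = a(1 − e^{−bx})` and `asymptotic`
`y = c − a·bˣ` (0 < b < 1); the bout-length/peak relation uses the logistic
`y = A2 + (A1 − A2)/(1 + (x/x0)^p)`.  All fits run from 10 deterministic
data-driven starts (amplitude from the data range, rates from a log grid
scaled by the x range, plus an early-slope heuristic) and keep the lowest
RSS, so they are reproducible without a seed; non-convergence is flagged,
not raised, and a constant response returns a degenerate result with the
obvious parameters.

## Synthetic recordings

The generator plants everything the analysis later measures.  Defaults
emulate a 2-h recording at 5-s sampling with a 1-h lethargus: alternating
sleep/motion bouts (exponential durations, mean 300 s each, floored at
130 s so planted bouts are detectable in principle; a fixed-duration
square-wave mode drives the segmentation benchmark), wake speeds lognormal
around 10 μm/s, quiescent jitter 0.2 μm/s, forward/reverse runs
(exponential, means 30 s / 10 s) with a slowly turning heading, nose 50 μm
ahead of the pharynx on a rigid 2-point body, pumping off exactly during
lethargus.  Calcium: per-neuron slow random-walk drift plus
double-exponential transients (rise 3 s, decay 30 s, GCaMP-like; no claim
of biophysical fidelity) of amplitude 1.0 ΔF/F (CV 0.2) at each sleep-bout
onset; an optional PVC-like neuron leads by 10 s; shot-like Gaussian noise
of 2% of baseline fluorescence.  Trial sets plant an additive ΔF/F effect
during stimulation and, for inhibition, a rebound transient at a configured
latency; the ground truth records the rebound peak as realized on the
sampling grid.  Rendering paints one Gaussian blob per neuron (σ 2 px) over
a flat background with a camera centered on the tracked neuron plus
integer-pixel jitter, amplitude proportional to raw fluorescence — so
extraction is exactly linear in planted amplitude.

Determinism: one root seed; each component (bouts, locomotion, calcium,
noise, camera) draws from its own fixed-offset substream, so enabling an
extra neuron or channel never perturbs existing draws, and identical
config + seed reproduces recordings byte-for-byte.

What the generator does **not** emulate: real body posture and
self-occlusion, tracking failures, photobleaching trends, correlated
(non-white) imaging noise, inter-worm variability in bout statistics, or
developmental drift across lethargus.  Passing the planted-truth benchmarks
therefore demonstrates correctness of the quantification rules, not
robustness to every artifact of real microscopy data.

## Benchmark problem sizes

The shipped property checks use sizes chosen to exercise each rule well
past its edge cases while staying desk-scale: 1,000 random length-50 traces
for the prominence oracle, full sign enumeration up to n = 10 and 2×2
margins up to 30, a 50-worm square-wave cohort (90-min recordings) for
segmentation recall/precision, 1,000 seeded replicates of 10-trial
experiments for type-I calibration and 100 for power, 100 replicates of
12-point dose-response fits, and a 200-frame 64×64 rendered stack for the
imaging round trip.
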