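# Methods

This note documents the models, parameter choices and numerical
conventions behind `dbsrecruit`, and what the synthetic-data tests do
and do not establish about real recordings.

## Experimental layout assumed

A miniscope session is a continuous recording at 15 Hz containing
`n_blocks` stimulation blocks (default 4, e.g. 0/100/200/300 µA) of
`trials_per_block` trials (default 8). Each 80-s trial holds 10 s of
pre-DBS baseline, 60 s of DBS, and 10 s post; trials are separated by a
10-s inter-trial interval and blocks by 30 s. All frame indices are
0-based with half-open windows `[on, off)`. Trials are aligned on DBS
onset (not trial start), so variable pre-roll in real data is
tolerated; trials whose aligned window would leave the recording are
dropped and counted.

## Normalisation

Traces are z-scored per neuron over the entire session with the
population standard deviation (ddof = 0): the formula Z = (x − µ)/σ is
applied as printed, with no degrees-of-freedom correction. Zero-variance
neurons cannot be normalised; they are flagged and excluded from
classification rather than silently zeroed, so downstream counts are
over classifiable neurons only. Z-scoring precedes any trial exclusion.

## Recruitment classification

Per neuron and block, per-trial means of the early/middle/late 20-s DBS
periods are paired with per-trial baseline means and tested with a
paired t-test across trials (trials are the pairing unit — per-trial
means rather than pooled frames, since frames within a period are
heavily autocorrelated while trials are exchangeable). The three period
p-values form a within-neuron family corrected by Holm–Bonferroni at
α = 0.05. Patterns map to classes: early-only → transient, all three →
sustained, none → none. Any other pattern (e.g. middle-only, or
significant periods with conflicting signs) is labelled `other` rather
than forced into a class; the two named classes never absorb ambiguous
neurons. Degenerate paired differences (zero variance) are treated as
non-significant and logged. Classification is invariant to adding a
constant to a trace and to trial order.

The Holm step-down procedure is implemented in-house (it is three lines
and part of the statistical recipe under test) and verified against
`statsmodels.stats.multitest.multipletests` on random vectors.

## Bootstrap machinery

All population nulls resample neuron *identities* without replacement
from the recorded population, preserving observed set sizes:

- **Consistency of modulation.** For each functional cluster
  (duration × sign), the statistic is the fraction of the cluster's
  neurons (any block) never assigned to a different cluster in any
  block. The null redraws, per block, as many neurons as were observed
  per cluster. A duration-only pooling (signs merged) is available as a
  companion output since the four-cluster treatment is one of two
  defensible readings.
- **Population overlap.** Observed P(B|A) = |A∩B|/|A|; the null redraws
  both sets uniformly. Its null mean equals the hypergeometric
  expectation |B|/|U|, which the tests verify.
- **Spatial clustering.** Observed statistic: mean over recruited
  neurons of the distance to the closest *other recruited* neuron
  (closest-neighbour rather than all-pairs, so short clustered
  distances are not averaged out by long ones). Both tails are
  reported: `p_clustered` (observed small) and `p_dispersed` (observed
  large). The test is invariant under translation, rotation and uniform
  scaling of the field of view.

p = (1 + X)/(N + 1), where X counts null samples at least as extreme as
the observation in the direction of the stated alternative (one-sided
"greater" for overlap and consistency, whose alternatives are
above-chance). N = 1000 by default. Glass's Δ standardises the observed
value by the null SD (ddof = 1 on the null sample). The 95% percentile
interval of the null is reported alongside; the p-value is primary.
All bootstrap results are bit-reproducible under a fixed seed.

## Resting-state and correlation metrics

The **cell-activity index** for a block is the per-neuron mean, over
full 60-s bins (trailing partial bins excluded), of the summed
deconvolved event amplitudes, averaged across neurons. The name
suggests a combination of an event-amplitude CDF with an event
frequency, but no standard combination rule exists; this package
implements the operational recipe (per-minute summed amplitudes
averaged across neurons) and additionally exposes the per-block
empirical amplitude CDF for side-by-side comparison. The index is linear in event amplitude and
additive over neurons.

**Spatiotemporal correlation** pairs every two neurons' Pearson
correlation over a frame window with their centroid distance; pairs with
a constant trace in the window are skipped and logged. The summary
curve averages correlation within log-spaced distance bins —
log-spacing is a display convention only; all statistics use linear
distances. A comparison helper returns per-bin differences between two
frame sets (e.g. DBS-on vs no-DBS).

## Behavior association

Events, grooming and locomotion are binned at 333 ms; at 15 Hz this is
exactly 5 frames, and for other rates the bin is `floor(bin_s × rate)`
frames. Grooming frames force locomotion to zero before anything else.
A bin is *grooming* if any of its frames is grooming; remaining bins are
split at the median of their binned locomotion — values at or below the
median are stationary, above are locomotion (ties go to stationary,
since only values strictly above the median count as movement).

Per neuron, a one-way ANOVA across the three categories is paired with
a Bayes factor from the BIC approximation, BF10 = exp((BIC0 − BIC1)/2),
which for the one-way layout reduces to
log BF10 = −(n·log(SSE1/SSE0) + (k−1)·log n)/2. This corresponds to a
unit-information prior, is monotone in the classical F statistic, and
needs no external Bayes-factor toolbox; it is labelled as an
approximation in the output metadata. Labels require both a significant
omnibus (p < 0.05) and BF10 > 3 before Tukey-HSD post-hocs are
consulted:

- grooming: grooming ≠ stationary and stationary = locomotion
- locomotion: locomotion ≠ stationary and stationary = grooming
- grooming-and-locomotion: both ≠ stationary and grooming = locomotion
- not-associated: non-significant omnibus and BF10 < 1/3
- anything else (1/3 ≤ BF ≤ 3, or a post-hoc pattern outside the rules):
  indeterminate

"Equal" means not rejected by Tukey at family α = 0.05. Labels are
invariant to uniform scaling of a neuron's event amplitudes.

## Wide-field pipeline

Motion correction registers every frame to the first by the argmax of
their 2D cross-correlation (FFT, circular boundary) and applies the
integer-pixel shift; subpixel refinement is deliberately out of scope.
A configurable shift-magnitude QC threshold substitutes for manual
inspection. ΔF/F is per pixel and per trial with F the mean over the
0.5-s window 9 s before DBS onset; the recording is partitioned into
per-trial segments at the baseline-window starts so every frame is
normalised (zero-baseline pixels are masked to NaN and counted).
Region curves are Gaussian-smoothed (σ = 2 px), mask-averaged and
z-scored per region over the whole recording; the sustained-suppression
score is the mean z over the last 30 s of each DBS period, averaged per
block, with a one-way region comparison plus Tukey post-hoc exposed as
utilities. Acquisition-side binning/downsampling is a property of the
input, not an operation; the pipeline accepts any H × W.

## Current-spread model

I = I0 + K·r² solved for r, with defaults I0 = 7 µA and K = 1292 µA/mm²
from classic microstimulation threshold measurements. The low end of the
plausible I0 range (7–22 µA) yields activation diameters of 0.54 mm at
100 µA and 0.95 mm at 300 µA (rounded to two decimals); sweeping I0
across the range brackets these values from above and below.
Currents below I0 return a flagged zero-activation result.

## Synthetic-session generator

The generator emulates the *outputs* of source extraction and
deconvolution, not raw video:

- **Baseline activity**: per-frame Bernoulli events at
  `baseline_event_rate_hz` (default 0.1 Hz) with exponential amplitudes
  (scale 1), convolved with a single-exponential calcium kernel,
  τ = 1.5 s (GCaMP6s-like; the simplest kernel adequate for classifier
  testing). The emitted event train is the planted train itself — no
  deconvolution is simulated.
- **Stimulation effects**: sustained neurons add a constant
  `effect_amplitude` (default 1.0 ΔF/F, a strong evoked response) over
  the full 60-s DBS period; transient neurons add a decaying box over
  the first 20 s (amplitude falling linearly to zero within the window,
  truncated at 20 s so the planted period structure matches the
  classifier's window definitions exactly). Inhibited neurons subtract
  the same waveforms. White Gaussian noise (SD 0.2 ΔF/F) is added last.
- **Class assignment**: each class owns a disjoint neuron pool sized by
  its maximum per-block fraction; within a block the first
  `round(f_b·N)` pool members are active. Nested activation keeps each
  neuron's duration and sign fixed across blocks, mirroring the
  consistent recruitment seen across stimulation intensities. Default
  fractions ramp from zero (block 0 = no-DBS control) to ~26% recruited
  in the top block. An `anesthetized` flag removes sustained (both
  signs) and transient-inhibited recruitment, leaving only
  transient-excited (antidromic-like) responses.
- **Spatial layouts**: random, Gaussian blobs (1/3/5 of decreasing
  size), annulus, or greedy farthest-point dispersion; non-recruited
  neurons are uniform over the field of view (400 px default).
- **Behavior**: grooming is a renewal process with geometric bout
  (mean 3 s) and inter-bout (mean 12 s) durations and a 10-frame
  minimum bout, targeting ~20% baseline grooming. During DBS-on frames
  of actively stimulated blocks each bout survives with probability
  `dbs_groom_suppression` (default 0.5). Locomotion is a rectified
  AR(1) speed forced to zero within grooming bouts. Behavior-tuned
  neurons (10% grooming, 10% locomotion, 5% both) have their event
  probability multiplied by `tuning_gain` (default 8) during their
  preferred behavior; the gain was set so that tuned neurons are
  unambiguously detectable at the default event rate, since no
  empirical effect-size statistics are available to emulate.
- **Wide-field fixtures**: a static spatial texture times per-region
  AR(1) activity fluctuations (2% fractional SD), with a planted
  multiplicative suppression ramp in one region and optional circular
  integer shifts.

What the synthetic tests show: that every estimator recovers what was
planted, at the stated sizes and noise levels, and that every null is
calibrated. What they do not show: robustness to real-data features the
generator omits — photobleaching and slow drifts, deconvolution errors,
overlapping/merged ROIs, non-Poisson burst statistics, behavior-
classifier false positives, and hemodynamic contamination in wide-field
signals.

## Problem sizes and numerical choices

Simulations in the test suite use 40–1000 neurons, 1–3 blocks and
500–1000 bootstrap replicates — large enough for the stated power and
calibration checks while keeping the full suite around a minute on one
core. Monte-Carlo assertions allow three binomial standard errors.
Transient-label recovery is structurally capped near ~93%: with a true
early effect, Holm still leaves a few-percent chance that a null
middle/late period is rejected, demoting the neuron to `other`; the
pooled recovery across planted classes exceeds 90%. Percentile CIs use
linear interpolation (numpy default); bubble sizes are −log10 p capped
at 10.

## Known limitations

- The Bayes factors are BIC approximations, not integrated Bayes
  factors with a stated prior; they agree with the classical F ordering
  but absolute values near the 3 and 1/3 thresholds should not be
  over-read.
- The consistency null treats cluster sizes as fixed per block; a null
  that also resamples sizes would be wider.
- The cell-activity index is one defensible operationalisation of an
  under-specified published measure (see above).
- Motion correction assumes rigid, integer, circular shifts; real
  non-rigid motion needs upstream tools.
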