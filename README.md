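# dbsrecruit

Analysis pipeline for quantifying how internal-capsule deep-brain
stimulation (DBS) reshapes single-neuron calcium activity and compulsive
grooming behavior in freely moving mice.

The package is aimed at researchers analysing block-structured DBS
experiments recorded with head-mounted miniscopes (per-neuron ΔF/F traces
and deconvolved event trains from source extraction) or wide-field
cortical imaging, together with frame-indexed behavior streams
(grooming classifier output, locomotion speed). Because raw recordings
of this kind are rarely shareable, the package ships a fully specified
synthetic-session generator with ground-truth labels, so every analysis
stage can be exercised and validated end to end without any data
download.

## What it computes

**Recruitment classification.** Sessions have four stimulation blocks
(e.g. 0/100/200/300 µA) of eight 80-s trials each, with 60 s of DBS per
trial starting 10 s in. Traces are z-scored per neuron over the whole
session, Z = (x − µ)/σ, and cut into trial windows aligned on DBS
onset. Per block, each neuron's per-trial mean in the early / middle /
late 20-s DBS periods is compared with its 10-s pre-DBS baseline by a
paired t-test (Holm–Bonferroni across the three periods). A neuron is
*transient* if only the early period differs, *sustained* if all three
do; the response sign (excited/inhibited) is the sign of the mean
difference. Dose–response curves and excitation/inhibition balance
(exact binomial test) summarise the population.

**Bootstrap statistics.** Population-level claims are tested against
resampling nulls that redraw neuron identities from the recorded
population: consistency of modulation across intensities (fraction of a
functional cluster's neurons never seen in another cluster), conditional
overlap of recruited populations P(B|A) = P(B∩A)/P(A), and spatial
clustering via the mean distance of each recruited neuron to its closest
recruited neighbour. All use N = 1000 resamples, the bootstrap p-value
p = (1 + X)/(N + 1) with X the number of null samples at least as
extreme as the observation, and Glass's Δ = (x̄ − µ_null)/σ_null as
effect size.

**Behavior association.** Events and behavior are binned into 333-ms
bins (5 frames at 15 Hz); each bin is grooming, stationary, or
locomotion (median split of non-grooming locomotion; grooming forces
locomotion to zero). Per neuron, a one-way ANOVA with a
BIC-approximated Bayes factor and Tukey-HSD post-hocs labels the neuron
grooming- / locomotion- / both- / not-associated.

**Wide-field preprocessing.** Rigid integer-pixel motion correction by
2D cross-correlation, per-trial per-pixel ΔF/F against a 0.5-s baseline
9 s before DBS onset, Gaussian smoothing (σ = 2 px), region-mask
averaging, per-region z-scoring, and a sustained-suppression score over
the last 30 s of each DBS period.

**Current-spread model.** The activation sphere around the electrode tip
follows the threshold-current relation I = I0 + K·r², with I0 = 7 µA
and K = 1292 µA/mm².

## Worked example

```python
from dbsrecruit import synth, recruitment, session

cfg = synth.SynthConfig(seed=1)          # 100 neurons, 4 blocks x 8 trials, 15 Hz
sess, truth = synth.generate_session(cfg)
tensor = session.align_trials(session.zscore_traces(sess))
labels = recruitment.classify_session(tensor)
print(recruitment.dose_response(labels).query("klass == 'any'")[["block", "count", "fraction"]])
```

prints

```
    block  count  fraction
4       0      3      0.03
9       1     10      0.10
14      2     18      0.18
19      3     23      0.23
```

i.e. recruitment rises dose-dependently from chance level in the no-DBS
block (3 false positives of 100 neurons at α = 0.05) to 23% of neurons
in the highest-intensity block, tracking the planted counts
(0/9/17/26 of 100 neurons). The numbered scripts under
`analysis/` walk through the full chain — current-spread model,
session simulation, recruitment, population bootstrap statistics,
behavior association, wide-field preprocessing, and the summary bubble
table — each printing what it found and writing tables under
`results/` (the bulky simulated session container goes to `scratch/`).

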