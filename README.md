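# icpop

Population analysis of two-photon calcium imaging recorded in the auditory
midbrain while head-fixed mice perform a go/no-go sound-detection task. The
package is aimed at systems-neuroscience analysts who have extracted ROI
fluorescence traces (e.g. from suite2p) together with a trial schedule and
lick timestamps, and want the full downstream chain: signal conditioning,
behavioural scoring, per-neuron task-modulation statistics, response-profile
clustering, and frame-by-frame population decoding of trial outcome — plus a
synthetic-session generator with known ground truth so every stage can be
validated end to end.

## What it computes

**Behaviour.** Trials are scored hit / miss / false alarm / correct
rejection from the first lick inside a 1.5 s response window. Sensitivity is
d′ = Φ⁻¹(HR) − Φ⁻¹(FAR), with a log-linear correction (+0.5 per cell) so
floor/ceiling rates stay finite, reported overall and in 10-dB sound-level
bins.

**Signals.** ΔF/F = (F − r·F_neu − F₀)/F₀ with neuropil coefficient
r = 0.7 and F₀ the whole-trace median; slow drift is removed by a
Gaussian + min/max morphological baseline; traces are sliced into
−2 s…+5 s trial windows (193–197 frames at ~28 Hz).

**Task modulation.** Per neuron, the response magnitude
mean(0…5 s) − mean(−2…0 s) is compared between hit and miss trials with a
Mann–Whitney U test on sound-level-balanced trial subsets;
sound-responsiveness uses a Wilcoxon signed-rank test on miss trials
(53–65 dB SPL). Both families are Benjamini–Hochberg corrected at q = 0.05.

**Clustering.** Each neuron's hit and miss trial averages (193 points each)
are concatenated into 386 features, reduced to 9 principal components, and
grouped by spectral clustering on a nearest-neighbour graph. Neighbour and
cluster counts maximise the mean silhouette
s_i = (b_i − a_i)/max(a_i, b_i), with a_i the mean intra-cluster distance
and b_i the mean distance to the nearest other cluster. Cluster composition
(lesioned vs non-lesioned animals) is tested with a two-sided one-proportion
Z-test against the population mix.

**Decoding.** At every frame, an L2 logistic regression classifies hit vs
miss from the population ΔF/F vector, trained with class weights
W_i = N_T/(N_C·N_i) and scored by balanced accuracy ½(TPR + TNR) under
nested stratified cross-validation (outer 5-fold; inner 4-fold randomised
search of the regularisation strength over log-uniform [10⁻⁴, 10²]). Only
intermediate-difficulty trials enter (the five sound levels centred on the
lowest level with d′ > 1.5) and only sessions with ≥ 15 hits and ≥ 15
misses. Stratified dummy models define chance (0.5); timewise comparisons
use Shapiro-gated one-sided tests with Bonferroni correction.

## Worked example

```python
import numpy as np
from icpop import synthdata, behavior, signals, modulation, decoding

params = synthdata.ScheduleParams(n_trials=300)
schedule = synthdata.sample_schedule(params, seed=1)
licks = synthdata.sample_behavior(schedule, synthdata.PsychModel(), seed=2)
outcomes = behavior.score_trials(schedule, licks)
summary = behavior.psychometric(outcomes)
print(f"hit rate {summary.hit_rate:.2f}, FA rate {summary.fa_rate:.2f}, d' {summary.dprime:.2f}")

rec, truth = synthdata.synthesize_session(
    schedule, licks, synthdata.default_prototypes(), n_neurons=40, noise_sd=0.05, seed=3)
dff = signals.compute_dff(signals.neuropil_correct(rec.F, rec.Fneu), rec.frame_rate)
dff = signals.remove_slow_baseline(dff)
tensor = signals.extract_trials(dff, schedule)

mod = modulation.analyze_session(tensor, outcomes, seed=0)
print(f"outcome-modulated neurons: {mod.n_significant}/{tensor.n_neurons}"
      f" (ground truth: {truth.outcome_coding.sum()})")

keep = signals.exclude_lick_contaminated_hits(outcomes, licks)
mask, levels = decoding.select_trials(outcomes, keep_mask=keep)
kept = mask[tensor.trial_indices]
labels = (outcomes["label"].to_numpy()[tensor.trial_indices][kept] == "hit").astype(int)
sub = signals.TrialTensor(tensor.values[kept], tensor.frame_rate, tensor.window,
                          tensor.onset_frame_index, tensor.trial_indices[kept])
res = decoding.decode_session(sub, labels, seed=0,
                              config=decoding.DecoderConfig(n_search=10, frame_stride=14))
pre = res.trained[res.frame_times < 0].mean()
post = res.trained[res.frame_times >= 0].mean()
print(f"balanced accuracy pre-stimulus {pre:.2f}, post-stimulus {post:.2f}, "
      f"dummy {res.dummy.mean():.2f}")
```

prints

```
hit rate 0.55, FA rate 0.03, d' 1.79
outcome-modulated neurons: 32/40 (ground truth: 32)
balanced accuracy pre-stimulus 0.91, post-stimulus 1.00, dummy 0.50
```

The behavioural model detects just over half the stimuli at these sound
levels (d′ ≈ 1.8). The modulation screen flags exactly the 32 neurons whose
generating prototypes distinguish hit from miss trials (the
behaviour-invariant cluster stays unflagged). The decoder reads the trial
outcome essentially perfectly after stimulus onset, and well above the 0.5
dummy chance level even before onset — the generator plants a pre-stimulus
state signal in one prototype, mimicking outcome-predictive network states.

A full multi-session run (simulate → preprocess → score → modulate →
cluster → decode → compare) is one command:

```bash
icpop run-all --seed 0 --out runs/demo
icpop report --run runs/demo
```

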