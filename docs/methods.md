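# Methods

This note documents the models and procedures implemented in `icpop`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish about real recordings.

## Task and data model

The analyses assume a go/no-go sound-detection session: click stimuli at
several sound levels (dB SPL) interleaved with catch trials (roughly one
trial in ten), inter-trial intervals drawn from a normal distribution with
mean 8 s and SD 2 s truncated below at 3 s, and a 1.5 s response window
after each onset. Licking within the window on a stimulus trial is a hit,
silence a miss; on catch trials, a false alarm or correct rejection. Neural
data are per-ROI somatic fluorescence traces with matched neuropil traces,
sampled at ~28 Hz (the pipeline accepts 27–30 Hz; a 7-s trial window then
spans 193–197 frames).

## Synthetic sessions

`synthdata` generates sessions with this exact statistical structure plus
full ground truth, so downstream statistics can be checked against a known
answer.

- **Schedule.** ITIs are exact truncated-normal draws — never clipped, since
  clipping would pile probability mass at the floor and bias the mean (the
  truncated mean at the defaults is 8.035 s, not 8 s). Catch trials (10 %)
  are placed uniformly at random; sound levels are assigned in a shuffled
  balanced design over the 9 default levels (41–65 dB in 3-dB steps).
- **Behaviour.** Hit probability is a logistic function of sound level,
  p = fa + (1 − fa − lapse)·σ(slope·(x − midpoint)), with defaults midpoint
  53 dB, slope 0.5 /dB, lapse 0.05, false-alarm rate 0.1 — values that put
  the d′ = 1.5 crossing mid-range so the trial-selection rule has room on
  both sides. Response latencies lie in (0.12 s, window]; 0.12 s is the
  animals' lick-latency floor. Anticipatory licks are planted at lags drawn
  from the ITI distribution itself (the learned expectation of the next
  trial), then removed from all response windows so that scoring is governed
  solely by the psychometric model.
- **Fluorescence.** Each neuron follows one of five response prototypes
  (sharp onset, sustained suppression, gradual late peak, behaviour-invariant
  sustained response, and a pure pre-stimulus state cell). On each stimulus
  trial the hit or miss kernel — selected by the scored outcome — is
  convolved with a unit-area single-exponential calcium impulse response,
  τ = 0.5 s (GCaMP6f-like; the kinetics are not otherwise modelled). On top:
  a per-neuron baseline (~100 a.u.), sinusoidal drift (amplitude 5 a.u.,
  period 300 s), a shared slow neuropil background scaled into the somatic
  channel by 0.7, and iid Gaussian noise (default SD 5 % of baseline). The
  pre-stimulus state adds ±gain/2 to the drive before onset on hit/miss
  trials respectively.
- **Not emulated:** pixel-level movies, motion artefacts, spike-to-calcium
  nonlinearity, correlated (shared-variability) noise between neurons,
  sound-level-dependent response amplitudes, slow behavioural state drift,
  and reward/licking motor signals. Passing tests therefore demonstrate that
  the *analysis chain* is correct and calibrated under its own assumptions,
  not that real IC data will show these effect sizes.

Default per-session trial count is 400 (configurable); nothing in the
analyses depends on it beyond statistical power.

## Signal conditioning

Corrected fluorescence is F − 0.7·F_neu; ΔF/F uses the whole-trace median
as F₀ (ROIs with non-positive median cannot be normalised and are dropped
with a warning). Slow drift is removed by subtracting
maxfilter(minfilter(gaussfilter(trace))) — Gaussian σ 10 s, min/max windows
60 s. These mirror common suite2p practice and are configurable; they pass
transients of a few seconds essentially untouched while removing
minutes-scale drift (verified spectrally in the tests; attenuation is
measured in RMS away from the filter edges, where reflection padding leaks).
Trial alignment maps time zero to the first frame at or after onset
(half-open convention); windows that would run outside the recording are
dropped, not padded. For pre-stimulus analyses, hit trials with any lick in
[−0.5 s, +0.12 s] around onset are excluded so licking cannot masquerade as
pre-stimulus coding.

## Per-neuron statistics

Response magnitude is mean ΔF/F over 0–5 s minus mean over −2–0 s. The
hit/miss comparison uses a two-sided Mann–Whitney U test on trial subsets
balanced per sound level (the majority outcome is downsampled without
replacement at each level, so outcome is not confounded with intensity).
The exact U null distribution is used for n ≤ 20 without ties, the
tie-corrected normal approximation otherwise; fully tied samples return
p = 1. Sound responsiveness uses a Wilcoxon signed-rank test of mean(−2–0 s)
vs mean(0–1 s) on miss trials at 53–65 dB SPL with at least 5 pairs. Each
family is Benjamini–Hochberg corrected, significant meaning adjusted
p < 0.05. Whether the hit/miss test should be one- or two-sided is a
genuinely open choice; two-sided is implemented since modulation in either
direction is of interest.

One balanced subsample is drawn per session with a logged seed. Because all
neurons in a session share that subsample (and trial windows of neighbouring
trials can overlap at short ITIs), sampling error is *correlated across
neurons*: occasionally a draw is imbalanced in a covariate shared by
similarly-tuned neurons, and several invariant neurons are flagged together.
The optional multi-draw mode (`n_draws > 1`, median p across draws) damps
the draw-level part of this. The false-flag property is therefore a
statement about expectation over sessions, and the test suite checks it on a
200-neuron session.

## Clustering

Features are the hit average followed by the miss average (2 × 193 = 386
columns), PCA-reduced to 9 components (an elbow-suggestion helper — largest
second difference of the scree — is advisory only). Spectral clustering uses
a k-nearest-neighbour affinity; the library symmetrises it as ½(A + Aᵀ),
which keeps an edge whenever either point names the other a neighbour, i.e.
union connectivity. A graph with more connected components than clusters is
an error with guidance to raise the neighbour count. The k-means step on the
Laplacian embedding runs with a fixed, logged seed.

Silhouettes are computed from the printed definitions (a_i: mean distance to
own cluster; b_i: minimum mean distance to another cluster; singleton
clusters score 0 by convention) and are evaluated in the same 9-D score
space the clustering sees — whether the original analysis used feature or
score space is unknowable from the text, so the space is configurable
(`silhouette_space="features"`). The grid search covers
n_neighbors ∈ {5,…,50}, n_clusters ∈ {2,…,15} by default; ties break to
fewer clusters, then fewer neighbours, for reproducibility. Composition
tests use a one-proportion Z-test per cluster against the population
lesioned fraction, with display proportions normalised so 0.5 = population
mix.

## Decoding

Features at frame t are the single-frame population ΔF/F vector — no
temporal windowing, matching the frame-by-frame design. Trial selection
anchors on the lowest sound level with d′ > 1.5 (session-wide FA rate,
per-level hit counts, log-linear correction) and takes the anchor ±2 level
ranks; at the edge of the level range the window truncates with a warning.
Sessions need ≥ 15 hits and ≥ 15 misses after selection.

The nested CV uses outer stratified 5-fold evaluation and, per outer fold,
25 random log-uniform draws of the L2 strength C ∈ [10⁻⁴, 10²] scored by
inner stratified 4-fold mean balanced accuracy (the inner fold count and
draw count are not dictated by the design; 4 folds is the natural choice on
an 80 % training split, and 25 draws samples the 6-decade range at ~4 draws
per decade). The winner is refit on the full outer-training set with class
weights W_i = N_T/(N_C·N_i) and scored on the held-out fold; the mean of
the five held-out balanced accuracies is the session's score at that frame.
The optimiser (lbfgs) runs with pinned tolerance 1e-4 and 1000-iteration
cap so reruns are bit-reproducible. Dummy baselines draw predictions at the
empirical class frequency, 100 repeats per frame with logged seeds.

Controls: neuron subsampling decodes with a fixed target population size
(the decode seed is held constant across draws, so drawing the full
population reproduces the full-session result exactly), and level matching
reuses the balanced subsampling to equalise hit/miss counts per sound level
before decoding.

## Timewise statistics

Session timecourses are linearly interpolated to a common frame count
(endpoints preserved) before testing. Per timepoint: trained vs dummy is a
one-sided paired test (t if the Shapiro–Wilk test does not reject normality
of the paired differences at p < 0.05, signed-rank otherwise); group vs
group is a one-sided unpaired test (t only if *both* groups pass the gate —
when the groups disagree the nonparametric branch is taken and logged; the
rule for that case is not dictated anywhere, and requiring both is the
conservative choice). Constant samples make Shapiro undefined and fall back
to nonparametric. Significance is p < 0.05 Bonferroni-corrected across the
tested timepoints; binning every b consecutive timepoints before testing
(used for small samples) shrinks the family by b and loosens the per-test
threshold accordingly.

## Numerical and scale choices in the test suite

Simulation-based tests run at deliberately small scale: sessions of
120–300 trials and 15–200 neurons, decoder calibration at 40 trials × 30
neurons over 60 replicates, familywise-error simulations with 20-test
families over 500–3000 replicates, and frame-by-frame decoding evaluated at
a stride of several frames where only the shape of the timecourse matters.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping the default suite around two minutes on one
CPU. Calibration bands (e.g. type-I error in [0.03, 0.07] at α = 0.05,
decoder null mean in [0.45, 0.55]) reflect those Monte-Carlo widths, not
extra tolerance in the implementations.

## Known limitations

- The generator's noise is white and independent across neurons; real
  two-photon noise is heavier-tailed and shared. Decoding accuracies on
  synthetic sessions are therefore optimistic.
- Trial windows (7 s) are longer than the shortest ITIs (3 s), so adjacent
  trials leak into each other's windows — as they do in the real task. The
  per-neuron statistics treat trials as exchangeable regardless.
- Image-plane QC (z-motion PCs, lick-triggered movies) returns scores and
  difference images; exclusion thresholds are left to the user, since the
  original screening was by visual inspection.
- Registration, segmentation and spike inference are out of scope; the
  pipeline starts from extracted traces.
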