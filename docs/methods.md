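# Methods

This note records the generative model, the feature definitions, the
selection and evaluation protocols, and the numerical and design
choices behind `erpscreen`, together with what the synthetic cohorts
can and cannot show about real recordings.

## Synthetic cohort model

Each record (one subject × electrode × stimulation mode) is

```
x(t) = Σ_b  s_b(t)  +  e(t)  +  n(t)  +  a(t)
```

* **Band processes** `s_b`: zero-mean Gaussian processes exactly
  band-limited to Delta (0.5–4 Hz), Theta (4–8), Alpha (8–12) or Beta
  (13–30), realized by drawing a white Gaussian spectrum, zeroing it
  outside the band, and inverse-FFT-ing. The realized power of each
  component is normalized to `baseline[b] · effect[b] · J`, with
  `effect[b]` the ADHD/control power ratio (defaults 1.5 / 1.5 / 1.0 /
  0.6 — the classic slow-wave-excess, Beta-deficit profile) and `J` a
  per-record log-normal jitter (log-SD 0.3, unit mean) standing in for
  between-record biological variability. Frequency-domain synthesis was
  chosen over time-domain filtered noise because finite-order
  generation filters leak power across band edges; with exact
  confinement, a planted ratio is recovered by the analysis filters to
  within a few percent instead of being diluted by ~20 %.
* **Baseline powers**: 25 / 16 / 9 / 4 µV² for Delta / Theta / Alpha /
  Beta — a roughly 1/f profile with ~8 µV background RMS, the order of
  magnitude of pediatric scalp EEG.
* **Evoked response** `e`: a 600-ms Hann-windowed sine cycle (biphasic,
  default 5 µV peak) added after each of the 20 % target stimuli of a
  200-stimulus oddball run at 1.5-s intervals. The shape is
  deliberately schematic: the pipeline's features measure band content,
  not ERP component morphology, so no attempt is made to model P300
  latency or topography.
* **Noise** `n`: white Gaussian, default SD 2 µV.
* **Artifacts** `a`: per record, `artifact_rate` square plateaus
  (~30 ms) set to ±`artifact_amplitude` (default 150 µV), guaranteed to
  trip the ±100 µV rejection rule.
* **Demographics**: gender and first-child are Bernoulli(½) unless a
  log-odds association with the class label is requested; by default
  they are pure noise features.
* **Duration**: one full run, `n_stimuli × isi` (default 300 s); all
  feature formulas are length-invariant in expectation, so scaled-down
  cohorts shorten runs by reducing `n_stimuli`.

Determinism: a cohort is a pure function of its `CohortSpec`
(including the seed); the pipeline's global seed fans out to per-stage
child seeds through `numpy.random.SeedSequence`.

What this model omits: 1/f-continuous spectra (power is banded, not a
smooth slope), non-stationarity, real artifact morphology (blinks,
muscle), electrode covariance and volume conduction, and any
subject-level trait structure beyond a shared power scale. Passing
tests therefore demonstrate that the *pipeline* recovers what it
assumes — planted band-power differences — not that the features would
separate clinical populations.

## Preprocessing

* **Artifact rejection**: the record is cut into 1-s segments (matching
  the spectral window); a segment containing any |x| > 100 µV sample is
  dropped and the survivors concatenated. Segment granularity preserves
  most of the data while honouring the threshold rule; the operation is
  idempotent, and a record with no surviving segment raises an
  `UnusableRecordError`. Independent-component cleaning of residual
  artifacts is out of scope: it is meaningless on synthetic
  single-channel records, and externally cleaned signals can simply be
  supplied as records.
* **Spectra**: Welch periodogram, 1-s Hann windows, 50 % overlap,
  density scaling (checked against Parseval on white noise).
* **Band filters**: order-6 elliptic bandpass designs applied
  forward-backward (`sosfiltfilt`), so features never see phase
  distortion. Passband ripple 0.1 dB, stopband attenuation 40 dB: with
  zero-phase application the magnitude response is squared, and a
  0.5 dB design would lose up to ~20 % of in-band power at ripple
  troughs; at 0.1 dB the double pass retains ≥ 94 % of any in-band tone
  while keeping stopband leakage below 10⁻⁴. Both parameters are
  arguments. Delta is given a 0.5 Hz floor so DC drift cannot dominate
  band power; the 12–13 Hz gap between Alpha and Beta is kept — no band
  covers it.

## The 26 features

Computed per record, per band (the per-band signal is the cleaned
record passed through that band's filter):

* **Wavelet (11)**: single-level db4 DWT splits the band signal into
  approximation (A) and detail (D) coefficients. `WT-ApCo` / `WT-DeCo`
  are mean squared coefficients (energy per coefficient — a scalar
  summary chosen because the downstream models need one number, and it
  is monotone in band energy). `ApEn` / `DeEn` are Shannon entropies
  (natural log; the base cancels in every ratio) of each set's
  normalized energy distribution; `TotalWE = ApEn + DeEn`;
  `R-ApEn`, `R-DeEn` divide by `TotalWE`; `ApEn-0`, `DeEn-0` divide by
  the pair mean; `ApEn-1`, `DeEn-1` divide by the pair maximum. The
  alternative normalization by the theoretical maximum ln N is
  available (`FeatureOptions.entropy_norm="theoretical"`); the pair-max
  reading is the default by parallel with the pair-mean features.
* **Band power (6)**: `ABP` = mean squared sample of the band signal.
  `RBP` = the band's percentage share of summed mean |amplitude| across
  the four bands (an amplitude share by definition; a power-share
  variant is available via `FeatureOptions.rbp_mode`). `ABP-0` and
  `ABP-1` normalize `ABP` by the across-band maximum and mean;
  `RBP-0` and `RBP-1` normalize `RBP` by the maximum and mean squared
  sample of the raw signal.
* **Fractal dimension**: Higuchi's estimator, k_max = 8; −slope of
  ln L(k) on ln k. A line gives 1, white noise → 2, a constant signal
  is defined as 1.
* **AR**: Burg fit of order 6 (short-segment-stable); the feature is
  the first (lag-1) coefficient, positive sign convention. A single
  scalar is used because the downstream screening treats "AR" as one
  feature; the full coefficient vector is available from the fitting
  routine if needed.
* **Peaks**: `PPA = max − mean`, `NPA = min − mean`. The "mid-point" is
  taken as the signal mean (median and mid-time-sample are defensible
  alternatives; the mean makes PPA/NPA exact mirror images under sign
  flip).
* **Summaries**: sum, mean, median of the band signal.
* **Demographics**: gender (F=0, M=1) and first-child (no=0, yes=1).

Identities that hold for every valid record (property-tested):
`R-ApEn + R-DeEn = 1`, `ApEn-0 + DeEn-0 = 2`,
`max(ApEn-1, DeEn-1) = 1`, `Σ_b RBP = 100`, `max_b ABP-0 = 1`,
`mean_b ABP-1 = 1`, `PPA ≥ 0 ≥ NPA`. Scaling a signal by c > 0 scales
ABP by c² and leaves all ratio features and FD unchanged.

## Feature selection

* **Screening**: every (band, feature, model) triple is cross-validated
  with the model trained on that single feature — 182 cells per band,
  728 in total. Folds are materialized once per band so all cells are
  compared on identical partitions. Zero-variance features still
  receive a cell (the classifier degenerates to majority voting) and
  are flagged.
* **Seeding**: per (model, band), all features screening *strictly*
  above 50 % form the seed pattern; if none qualifies, the single best
  feature is used and the fallback logged.
* **Greedy search**: hill-climbing over the neighborhood {remove one,
  add one, swap one in for one out}. A move is accepted only if pooled
  CV accuracy strictly improves; among equal improvements the smaller
  pattern wins, then canonical feature order — the search is a
  deterministic formalization of the manual add/remove/replace
  refinement a practitioner would run, and is reproducible given the
  folds. Termination: no improving neighbor, or `max_iter` sweeps.
  Neighbors of the final pattern within `tie_tolerance` of its accuracy
  are reported as equivalent alternatives.

Because the search optimizes CV accuracy, its in-search accuracy is
optimistically biased. The evaluation stage therefore supports
re-scoring searched patterns on fresh folds (the demo's stage 5 does
exactly this and prints the gap); on null data the searched-pattern
accuracy distribution directly exposes that selection optimism.

## Classifiers and evaluation

The seven families, delegated to scikit-learn with the study's stated
hyperparameters: linear-kernel SVC; a 50-hidden-layer rectifier MLP
(width 16 per layer by default — width is not part of the stated
architecture and is configurable); unpenalized binomial GLM (logit
link, 0.5 threshold); L2 logistic regression; entropy-split decision
tree of max depth 20; 100-tree random forest of max depth 10;
Gaussian naive Bayes. Two substitutions are forced by the estimator
library: gain-ratio splitting is unavailable, so entropy-based
information gain stands in for both tree models; and the Laplace count
correction applies to categorical likelihoods, which have no analogue
in a Gaussian event model for continuous features. Scale-sensitive
estimators are wrapped with a within-fold standardizer.

A practical note on the deep model: a 50-layer plain feed-forward ReLU
network does not propagate gradient or signal at these widths and
sample sizes — it reliably collapses to majority-class prediction in
a handful of epochs. This is an honest property of the stated
architecture in a standard MLP implementation; the registry keeps it
(the collapse is itself informative, and it is cheap), and its rows
simply sit at chance.

* **Cross-validation**: stratified 10-fold by default. Because each
  subject contributes 6 records, record-level folding leaks subject
  identity between train and test; the default is therefore
  subject-grouped stratified folds, with `CVSpec(grouped=False)`
  reproducing the leaky record-level protocol. A single stratified
  70/30 holdout (`mode="holdout"`) is also provided, since both
  protocols are in common use and they answer slightly different
  questions. Fold counts should divide the per-class subject count:
  unbalanced folds bias pooled null accuracy below 50 % (the familiar
  finite-sample anti-learning effect), which the null-calibration tests
  avoid by choosing divisors.
* **Metrics**: accuracy, precision, classification error (percentages),
  sensitivity, specificity from the pooled out-of-fold confusion
  matrix, positive class = ADHD. Ratios with zero denominators are
  reported as undefined (`None`), never as 0.
* **ROC/AUC**: threshold sweep over pooled out-of-fold scores
  (probability of ADHD, or the signed SVM margin), trapezoidal AUC;
  equal to the normalized Mann–Whitney U statistic (tested to 1e-9).

## Problem sizes

The default design (60 subjects, 300-s records) runs the full pipeline
in well under an hour on one CPU; the test suite and the acceptance
script use scaled-down cohorts — 6–10 subjects per group and 15-s
records, 2- to 10-fold CV — which exercise every stage identically and
keep the whole suite at a few minutes. The demo analysis under
`analysis/` uses the 12-subject scale and states it in its output.

## Known limitations

* Synthetic validation only: no claim transfers to clinical data
  beyond "the pipeline recovers what the generator plants".
* The wrapper search shares data between selection and evaluation
  unless patterns are re-scored on fresh folds; both numbers are
  reported, neither is privileged.
* `AR` compresses an order-6 fit to its first coefficient; bands whose
  discriminative information sits in higher-lag structure are
  under-served by design.
* The Alpha–Beta gap (12–13 Hz) and the Delta floor (0.5 Hz) mean the
  four bands do not partition the spectrum; broadband power is not
  conserved across band features, and `Σ band ABP < raw ABP` for
  broadband signals.
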