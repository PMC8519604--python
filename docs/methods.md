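# Methods

This note documents the modeling and numerical choices behind the package:
what each stage assumes, which knobs matter, what the synthetic generators do
and do not emulate, and where the design was genuinely open.

## Problem setting

Cross-subject transfer for two-class EEG mental-state classification.  Each
subject is one *domain*; N subjects with labeled segments are sources, one
subject is the unlabeled target.  The goal is a classifier for the target
that never sees a target label.  Individual spectral differences between
subjects (electrode coupling, skull/physiology, baseline band power) shift
the feature distributions enough that a classifier pooled over sources
degrades on a new subject; the method counteracts this with feature-level and
prediction-level alignment.

## Spectral features

* Windows: 0.5 s, non-overlapping, trailing partial window dropped.  At
  200 Hz a window holds 100 samples; with 61 channels a raw segment has
  6100 values.
* PSD: single-window periodogram (each 0.5 s segment is one analysis unit, so
  no Welch averaging), boxcar window, per-window mean removal (standard
  periodogram practice for finite windows).  A 100-sample window natively
  yields 2 Hz bins, while the band definitions live on a 1 Hz integer grid;
  each window is therefore zero-padded to `fs` samples (1 s) before the
  transform, which evaluates the same periodogram on an exact 1 Hz grid.
  This is an interpolation of the spectrum, not added information; it is the
  simplest mechanism that produces a reading at every integer frequency.
* Log scale: log10, with power floored at 1e-12 beforehand so silent
  channels produce the finite floor value rather than −∞.
* Bands: θ 4–7, α 8–13, β 14–30 Hz with **inclusive** integer edges — 4, 6
  and 17 points, 27 per channel, 1647 for 61 channels.  Ordering is
  channel-major: per channel, bands in the given order, ascending frequency
  within a band.
* Band-pass: optional zero-phase 4th-order Butterworth (default 1–30 Hz, on
  for raw EEG).  The analysis bands stop at 30 Hz, so the filter mostly
  removes drift and line noise rather than shaping the features.  Its
  transient at the 1 Hz edge spans roughly a second; recordings are expected
  to be much longer than that.

## Synthetic cohort generator

The simulator emulates the *structure* of a multi-subject fatigue study: 15
subjects, 61 channels at 200 Hz, 700 awake + 700 fatigue half-second segments
per subject (1400 × 1647 features per subject, 21 000 segments per cohort).

* Noise: Gaussian white noise shaped 1/f in amplitude ("pink"), the standard
  first-order approximation to resting EEG spectra; a white option exists for
  debugging.
* Class effect: multiplicative band-power gains applied in the frequency
  domain.  Defaults make fatigue raise θ power (gain 2.2) and α power (1.6)
  and slightly lower β (0.9), the direction reported for mental fatigue;
  magnitudes are free choices at a level the PSD pipeline detects reliably
  without being trivial.
* Subject shift: per-channel log-normal gains plus per-subject log-normal
  jitter of the band gains (sd 0.25 for both by default).  This mimics
  between-subject amplitude and band-power differences without modeling
  their physiology.
* Not emulated: volume conduction / channel correlation structure, eye-blink
  and muscle artifacts, non-stationarity within a session, task-evoked
  transients.  Passing tests on this cohort therefore show that the pipeline
  and the adaptation machinery work under realistic geometry and a plausible
  shift model — not that the accuracy figures transfer to real recordings.
* Target labels are returned in a structure separate from the training
  inputs, so no training code path can read them.

## Blob benchmark generator

For fast loss/optimizer experiments: isotropic Gaussian classes with a shared
mean layout, each domain transformed by its own random affine map.  The
translation has per-coordinate sd equal to `domain_shift_scale`; the rotation
is kept mild (typical plane angle ≈ 0.2 × scale radians) **by design** —
large random rotations can swap the class geometry outright, producing
targets that contradict their sources, which no unsupervised adapter can
recover from and which between-subject EEG variation does not resemble.
Covariate shift here means "same class structure, displaced clouds".

## Backbone

All three stages are fully connected: shared extractor
`relu(W₂ relu(W₁x + b₁) + b₂)` into the common space, one
`relu(Wₙ · + bₙ)` subnet per source into the specific space, and one affine +
softmax head per source.  Dense layers suit the input — a fixed grid of band
log-powers, not a raw waveform — and keep the multi-head gradient flow easy
to audit (a parameter update from head *n*'s loss touches only `f`, `Fₙ`,
`Oₙ`).  Inputs are standardized per feature with statistics fitted on the
pooled source domains (the target reuses source statistics, keeping it fully
held out); without centering, the log-power offsets leave the network at the
uniform-output saddle.  Heads are initialized with small random weights: an
exactly-zero head passes no supervised gradient to the lower layers on the
first steps, during which the alignment terms would happily collapse the
feature space.  Softmax is computed with a detached row-max shift (exact, by
shift invariance).

The gradient machinery is a compact in-package reverse-mode autodiff layer
over numpy arrays (float64), covering exactly the operator set the model and
losses need, with an Adam optimizer; gradients are verified against central
differences in the test suite.

## Alignment losses

* Kernel: Gaussian, multi-bandwidth — `{median pairwise distance × 2^k,
  k = −2..2}` recomputed per batch (the standard median heuristic ladder).
* Local label-conditional MMD: per class, weighted kernel sums with source
  weights `1/n_c` and target weights `p_i^c / Σ_j p_j^c` from classifier
  *n*'s probabilities when aligning source *n* (pairwise self-consistent; an
  ensemble averaging option exists).  Two scalings are provided: the default
  `weighted` mode uses the normalized weights alone — since each class's
  weights already sum to one, adding 1/|X|² pair-count prefactors would
  shrink the loss by batch-size² and make its scale depend on batch size —
  while `literal` mode keeps those prefactors for completeness.  Pseudo-label
  weights are treated as constants per step (detached), so the loss cannot
  reinforce its own soft labels through the weighting.
* Classes absent from both sides of a pair contribute zero and are flagged;
  a class present on only one side contributes its one-sided terms.
* Global loss: the pairwise discrepancy `d_nm` (mean L1 distance between
  probability rows, range [0, 2]) is the scalar that both defines and weights
  the pair terms; the similarity weights `ω_mn = d_nm / Σ_{j≠n} d_nj` are
  vector-valued in spirit but must be scalars to weight scalars, so the same
  `d` statistic is used in the numerator and denominator.  Weights are
  treated as constants in the gradient.  For N = 2 the row normalization
  forces ω = 1 and the weighted loss vanishes identically; the implementation
  falls back to the unweighted pair discrepancy with a warning so two-source
  training still receives a consensus signal.

## Training

* Objective: `L_total = L_c + μ L_local + γ L_global` with `L_c` the sum over
  domains of the mean cross-entropy (probabilities clamped at 1e-12).
* Defaults: Adam at learning rate 0.001; batch 64 per domain per step; 500
  iterations; μ = γ = 0.5 with a linear 0→target ramp over the first 25 % of
  iterations (on by default — early pseudo-labels are noise, and full-strength
  alignment before the classifiers warm up can collapse features).
* Auxiliary ratio λ ∈ [0, 1]: the fraction of unlabeled target samples made
  available to the alignment terms (default 1.0); the held-out evaluation
  always uses all target samples.
* Batches are drawn uniformly per domain (not class-balanced); with the
  label-conditional loss averaging over present classes, occasional class
  imbalance in a batch is tolerated rather than corrected.
* Randomness: three independent seeded streams (batch schedule, auxiliary
  pool, dropout) plus a seeded initializer, so ablations that disable one
  consumer leave the others' schedules untouched and runs are bit-reproducible
  on one thread.
* Prediction: ensemble weight of classifier n ∝ Σ_{m≠n}(1 − ω_mn) (agreement
  proportional), uniform averaging as a fallback option; argmax ties break
  toward the lower class index.
* Metrics: accuracy, precision, recall, F1 from the confusion matrix with the
  fatigue class (label 1) as positive, reported in percent.
* Stopping: fixed iteration budget — with no target labels there is nothing
  to validate against.

## Benchmark experiment sizes

The frozen benchmarks (`eegmsda.benchmarks`) fix the experiment conditions:

* Blob adaptation: 6 domains (5 sources), 2 classes, 100 samples/class,
  10 dimensions, separation 3.0, shift 1.5, batch 32, 500 iterations, three
  seeds, full objective vs μ=γ=0 ablation.  Shift 1.5 puts the source-only
  model visibly below ceiling (high-80s/low-90s accuracy) so the adaptation
  effect is measurable.
* Synthetic LOSO: the full 15-subject, 61-channel cohort geometry with 120
  segments per class per subject and batch 16 — the cross-subject structure
  is what the experiment tests; segment count only sets how finely the
  per-subject distributions are sampled.

## Known limitations

* The synthetic cohort's shift model is multiplicative-spectral only; methods
  that exploit channel covariance would see an unrealistically easy problem.
* The backbone is dense; no convolutional variant is provided, and
  architectures beyond layer widths are not configurable.
* The MMD estimator is the biased V-statistic (quadratic in batch size);
  linear-time estimators are out of scope.
* Wall-clock performance targets CPU-scale experiments; there is no GPU path.
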