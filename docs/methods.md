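# Methods notes

This document records the modeling choices behind `seegstate`: what the
synthetic data emulate, how each pipeline stage is defined, which knobs
matter, and where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The task and its labeling rule

The package targets binary speech-state detection: classify short
windows of multichannel intracranial signal as *rest* or *overt speech*.
Sessions follow a sentence-reading paradigm; each trial is preparation
(1.5–2.0 s, uniform), reading (syllable intervals, capped at 10 s), and
rest (2–3 s, uniform). Speech is the span from the first syllable onset
to the last syllable offset, **including intra-sentence pauses** — a
deployed speech gate must not disengage during a breath or a planning
pause. Rest is everything else within the trial. Two labeling spans are
genuinely ambiguous:

* *Post-utterance rest.* We label the trailing rest phase (after the
  last syllable offset) as rest. The alternative — treating everything
  after first onset as speech — would make the gate latch on forever;
  we bound speech at the last syllable offset.
* *Boundary windows.* In the discretized protocol, a window straddling
  a rest/speech boundary has no clean label and is dropped. The
  continuous protocol instead labels every window by the state at its
  final time point, which is the causally correct convention for a
  streaming detector.

## Synthetic sessions

Real SEEG cannot be shipped, so the generator produces sessions with
the statistical structure the analysis relies on:

* **Background**: 1/f^α Gaussian noise (α = 1.0 by default, unit SD),
  synthesized by spectral shaping of white noise. Intracranial spectra
  are broadly power-law; α is configurable because empirical slopes
  vary by region and reference.
* **Line interference**: 50 Hz mains plus 100/150/200 Hz harmonics with
  decreasing amplitudes (0.5/0.25/0.12/0.06 of the background SD) and
  random phase per channel — the reason the notch bank exists.
* **State-dependent components** on informative channels only: a
  low-frequency (2–30 Hz) band-limited amplitude modulation and a
  high-gamma (75–150 Hz) band-limited power increase, both gated by the
  speech state and scaled by the channel's `snr` (each contributes
  `0.7·snr` SD while active). These mirror the two signatures the
  decoder is meant to exploit: slow motor/preparatory dynamics and
  high-gamma correlates of local firing.
* **Gating ramps**: the gate uses 50 ms raised-cosine ramps rather than
  steps; physiological transitions are not discontinuities, and step
  gating would inject broadband edge artifacts that make the
  classification task artificially easy at the exact boundary.
* **Pauses**: inserted between syllables with probability 0.3,
  0.2–0.6 s long, and labeled speech per the rule above.
* **Audio**: an envelope-only surrogate (one Hann bump per syllable);
  it exists to exercise the audio–neural independence screen and the
  labeling machinery, not to model acoustics.
* **Montage**: channels carry region/domain/tissue metadata spanning
  cortical gyri and subcortical structures (thalamus, amygdala,
  hippocampus), plus at least one occipital and one white-matter
  contact in default montages so the exclusion rules are exercised.
  Informative channels alternate between cortical and subcortical
  regions (or follow an explicit region list, as in the
  region-exclusion cohort).

What the simulator does **not** model: volume conduction and channel
covariance, non-stationary artifacts, behavioral variability in
utterance timing beyond uniform draws, acoustic contamination of
high-frequency bands, and realistic phonetics. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its
statistics behave as designed — not that clinical-recording accuracies
would reach the same values.

Class proportions (rest vs. speech windows) are not fixed by the
paradigm constants; they emerge from syllable counts and phase
durations and are configurable through the paradigm config.

## Preprocessing

* **Filters**: family and order are not pinned down by the protocol
  constants, so we use 4th-order Butterworth designs (low-pass 200 Hz
  for broadband, band-pass 75–150 Hz for high-gamma) and IIR notches
  with quality factor Q = 30 at 50/100/150/200 Hz. Offline stages apply
  them forward–backward (zero phase); the continuous path applies the
  identical designs forward-only so no future samples influence a
  prediction.
* **Z-scoring** is per channel with statistics computed on the
  training-split trials and frozen for evaluation and streaming —
  computing them on the full recording would leak evaluation data.
  Zero-variance channels are flagged and dropped, never passed through.
* **Decimation** 2,000 → 500 Hz is plain integer-factor subsampling
  after the 200 Hz low-pass. Content up to 200 Hz sits below the 250 Hz
  post-decimation Nyquist, so no extra anti-alias filter is inserted;
  the margin is slim but valid.
* **Windows** are 100 ms, i.e. T = 50 samples at 500 Hz.

## Channel selection

Each trial contributes one paired observation per channel: mean Welch
power (4–150 Hz) during the utterance versus during the immediately
preceding silence, matched in duration and truncated at the trial
start. Welch uses 1 s Hann windows with 50 % overlap (≥ 2 Hz resolution
across the band; the window shrinks for shorter intervals). Powers are
averaged in linear units; averaging in dB would weight low-power bins
more heavily and is a defensible alternative we did not take. The
paired t-test is two-sided; identically zero paired differences return
t = 0, p = 1 by convention. Benjamini–Hochberg FDR runs across channels
at α = 0.05. Occipital contacts (visual activity time-locked to reading
the displayed sentence) and white-matter contacts are excluded
regardless of significance. Low-SNR screening by visual inspection is
replaced by the zero-variance rule — subjective screening is not
modeled.

## The classifier

The architecture is deliberately plain — no normalization layers, no
residual connections: stem conv (kernel 15, stride 4, 32 filters),
three blocks of same-padded conv (kernels 7/5/5; 64/128/256 filters) →
ReLU → max-pool (kernel 2, stride 2) → dropout 0.1, then global average
pooling over time and a single-logit linear head read through a
sigmoid. Same padding is forced: with T = 50 the stem leaves 13 time
steps and the pooling cascade 13 → 6 → 3 → 1; unpadded convolutions
would collapse the tensor before the last block. Binary cross-entropy
on one sigmoid logit is equivalent to a two-way softmax with fewer
parameters.

The implementation is pure NumPy (float64): im2col convolutions with
hand-derived backward passes, verified against central finite
differences to ~1e-9 relative in the tests. This keeps the package
dependency-light, bit-reproducible on CPU, and makes the input
gradients needed for saliency exact rather than framework-dependent.

Training: Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999) with weight decay 5·10⁻³
folded into the gradient, batch size 48, cosine decay
`lr(e) = 0.5·lr₀·(1 + cos(πe/E))`, early stopping after 5 epochs
without validation-loss improvement, best-checkpoint restore. The
validation set for early stopping is a 20 % sentence-level carve-out of
the *training* sentences, leaving the evaluation split untouched.
Because speech windows outnumber rest windows, every split is balanced
by seeded subsampling of the majority class, which makes the 50 %
chance baseline exact.

## Evaluation

Splits are at sentence level: all repetitions of a sentence fall on one
side, and a leakage guard (`SplitSpec.validate`) runs inside every
experiment, not only in tests. Discretized accuracy is the fraction of
correctly classified balanced held-out windows, aggregated over split
seeds as mean ± SD.

Continuous decoding advances a 100 ms window in 5 ms steps (95 %
overlap). At 500 Hz a 5 ms step is 2.5 samples, so window starts are
laid out in seconds on the 5 ms grid and mapped to the nearest sample,
giving alternating 2/3-sample hops; this preserves the printed step
size exactly at the cost of a ±1 ms jitter. Each window is scored
against the ground-truth state at its final sample; accuracy is
aggregated **per sentence trial** — adjacent windows share 95 % of
their samples and must not be treated as independent observations. The
decision threshold stays at 0.5 with no smoothing or hysteresis.

Statistical wrappers implement the comparisons used throughout the
analyses: one-way ANOVA with Tukey HSD, fixed-effects two-way ANOVA
with interaction and Bonferroni-corrected simple effects, one-sample
t-tests against the 50 % baseline (zero-variance input handled
explicitly), and two-group t-tests with optional Bonferroni correction.

## Ablations and saliency

Random dropout removes `round(f·C)` channels uniformly at random,
redrawn per seed, at f ∈ {0, 0.1, 0.3, 0.5}. Region exclusion removes
every channel in the classical speech set {angular, superior/middle/
inferior frontal, superior/middle/inferior temporal, precentral}.
Domain restriction keeps only cortical or only subcortical channels and
errors out (rather than silently training an empty model) if none
exist. Every condition retrains from scratch and reuses the same split
seeds so comparisons are paired.

Saliency is `ζ(c) = (1/T) Σ_t |∂L/∂x_{t,c}|`, averaged over all
evaluation-split segments of both classes with dropout disabled (the
segment set entering the average is a free choice; a speech-only flag
would be a one-line change). ζ is min-max normalized across channels
within a run and aggregated per region as the unweighted mean over that
region's channels. Normalization is order-preserving, so rankings are
identical pre- and post-normalization.

## Problem sizes and numerical choices

The shipped experiments run at desk scale: the acceptance cohorts use
30 sentences × 3 repetitions (90 trials), 40 channels and 30 training
epochs over 5 split seeds, and the slow test-suite cohort uses
12 sentences × 3 repetitions with 16 channels over 20 seeds. These
sizes keep a full run in the minutes range on a single CPU while
leaving hundreds of balanced windows per evaluation split. One
simulated session is shared across split seeds within a cohort: a
participant contributes a single recording, and variability across
seeds reflects the splitter and the training stochasticity, not fresh
data.

Other numerics: interval arithmetic uses a 1e-9 s tolerance at window
boundaries; 1/f noise is synthesized at the next fast FFT length and
truncated; filters run in float64 and signals are stored float32;
per-stage seeds derive from the global seed via CRC32 of
`"{seed}:{stage}"` (stable across platforms, < 2³¹), so re-running any
single stage reproduces the full-pipeline draw.

## Known limitations

* The simulator's independence across channels means channel dropout is
  "easier" than in real recordings, where informative channels are
  correlated; robustness results should be read as machinery checks.
* Continuous decoding reuses models trained on zero-phase-filtered
  segments while streaming inputs are causally filtered; the small
  distribution shift is intentional (it matches how such a system would
  be deployed) and is visible as the discretized-vs-continuous gap.
* The high-gamma pathway shares the notch bank with the broadband
  pathway, so a 100 Hz narrowband component is removed in both modes.
* No re-referencing (bipolar/Laplacian) or artifact rejection beyond
  flat-channel removal is implemented.
* EDF export is not provided; recordings round-trip through an HDF5
  container and annotations through tab-separated text.
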