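# Methods

## The measurement

`semgaze` measures *semantic uncertainty* — how undecided a group of
listeners is about the meaning of an ambiguous word — as a function of
time during spoken-sentence comprehension. The paradigm it models is a
gaze-contingent choice task: four candidate meanings (two senses of the
ambiguous word plus two related distractors) sit on a ring of 10° radius
that rotates rigidly at 5°/s, and each listener continuously fixates the
meaning they currently prefer. Momentary choices are read off the gaze:

1. **Eye selection.** Right-eye samples by default; the left eye is
   substituted per sample where the right sample is missing or invalid.
2. **Artifact filtering.** Samples are dropped when they fall outside the
   screen (half-extents 19.8° × 12.7°, a 72 × 45 cm display at 100 cm) or
   when the centered-difference angular speed exceeds 25°/s (saccades).
   End samples use one-sided differences.
3. **Assignment.** A retained sample selects the option whose bounding
   box contains it at that instant. Boxes are axis-aligned, centered on
   the rotating option, and expanded by one character size (1.2°) on
   every side: width `(label_length + 2) × 1.2°`, height `3 × 1.2°`; the
   boundary counts as inside. A sample in several boxes goes to the
   nearest box center, with exact ties to the lower option index.
4. **Pooling and entropy.** Choices of all participants are pooled in
   half-open bins (100 ms default, 500 ms as a robustness resolution)
   tiling the sentence plus a 5 s post-sentence tail. Per bin,
   `H = −Σ p(xᵢ) log₂ p(xᵢ)` over the four options, in [0, 2] bits.
   Unassigned samples are excluded from numerator and denominator; an
   empty bin is *missing* (NaN) and is skipped by every downstream
   average — no interpolation, which would bias entropy downward.

## Inferential layer

* **Segments.** Initial = first half of the sentence, late = second
  half, post-sentence = the 5 s tail. In-sentence segment means average
  entropy at the bins containing word onsets (bin-of-onset by floor);
  the post segment averages all bins, as no word onsets occur there.
  A trial-level one-way repeated-measures ANOVA compares the segments,
  with Bonferroni-corrected paired t-tests and paired Cohen's
  d = mean(diff)/SD(diff).
* **Event-locked test.** Per trial, mean entropy in the 1 s windows
  before vs after the ambiguous word's onset; paired t over trials.
  Because uncertainty declines globally, significance is assessed
  against a permutation null: per iteration one timepoint is drawn
  uniformly in each trial (restricted to where both windows fit — trials
  violating this are excluded from observed and null alike), the same
  paired t is computed, and `p = (1 + #{null ≥ observed}) / (1 + N)`
  with N = 10,000 by default. The bin containing a timepoint starts the
  post window.
* **Reduction rates.** Per trial, `(initial mean − post mean) / sentence
  length`. The denominator is characters: with entropy differences near
  1 bit and ~31-character sentences this puts rates at the 0.02–0.04
  bits/character scale on which the group statistics operate; seconds
  are available as an option. A between-trial one-way ANOVA over the six
  bias levels is followed by Tukey HSD (studentized range;
  Tukey–Kramer harmonic-mean convention for unequal groups) with
  pooled-SD Cohen's d.
* **Linearity (ΔM).** ΔM1 = (M₀ − M₀.₂) − (M₀.₂ − M₀.₄) and
  ΔM2 = (M₁ − M₀.₈) − (M₀.₈ − M₀.₆) over level means; trials are
  resampled within level (10,000 bootstrap draws), CIs are percentile
  95%, and `p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))` with the +1 convention so
  no p is exactly zero.
* **Turning points.** A continuous piecewise-linear model (default 3
  segments / 2 breakpoints — plateau, decline, plateau) is fitted per
  profile, breakpoints restricted to the bin grid and found by
  exhaustive search minimising SSE with a minimum of 3 bins per segment.
  The turning point is the start of the steepest-declining segment; a
  profile whose steepest slope is not negative is flagged `no_decline`.
  One-way ANOVAs ask whether bias level shifts the turning point or the
  slope.
* **Mixed design.** A 3 (segment, within-trial) × 6 (bias,
  between-trial) mixed ANOVA plus per-segment simple-effects ANOVAs.
  η² is reported both as SS_effect/SS_total and as partial
  SS_effect/(SS_effect+SS_error), since the two diverge in the mixed
  design.

Repeated-measures and mixed ANOVAs are computed by pingouin, the one-way
ANOVA by pingouin, Tukey HSD by statsmodels, and t-tests/correlations by
scipy; the test suite checks all of them against brute-force
sums-of-squares oracles. The resampling machinery — permutation null,
bootstrap ΔM, breakpoint search — is implemented in this package.

## Model-side uncertainty

For a masked language model, uncertainty is geometric: reference sense
embeddings `ref_A`, `ref_B` are the mean contextual embeddings of the
ambiguous word over sense-annotated sentences; a word embedding `e` is
projected onto the axis, `t = ⟨e − ref_A, ref_B − ref_A⟩ / ‖ref_B −
ref_A‖²`, and `U = 1 − |2·clamp(t, 0, 1) − 1|` — 0 at either sense, 1 at
the midpoint, linear between, with coordinates beyond a reference
clamped (U is defined only between the senses). Revealing the sentence
one character at a time (all later characters masked, the ambiguous word
always visible) yields a per-step series; multi-character words are
mean-pooled over their token states.

Comparison with human profiles is offered in two modes, because the two
natural readings of "correlate the concatenated sequences" differ in
their degrees of freedom: `per_trial_mean` correlates one mean per trial
(df = trials − 2); `resampled_concat` maps steps to seconds through the
word-onset timestamps (characters spread uniformly within each word's
interval), interpolates the model series onto the human bin grid inside
the sentence, concatenates all trials and correlates the pooled vectors.

The embedding backend is a contract (`embed_word_in_context`,
`embed_word_in_full_sentence`, fixed dimension, deterministic). All
tests and simulations run on `SyntheticEmbeddingProvider`, which plants
two orthogonal anchors and moves the word embedding linearly from the
midpoint toward the sentence's latent sense coordinate as the visible
prefix grows, with hash-seeded (bit-reproducible) noise. The
`semgaze.adapters.bert` module implements the same contract over a
transformers masked LM (`semgaze[bert]` extra); when the tokenizer
merges characters, every token overlapping the word span is pooled from
the final hidden layer — a documented adapter choice, not an asserted
ground truth.

## The synthetic generator

No raw data accompany the paradigm, so the generator is a first-class
module that plants exactly the statistical structure the analysis is
meant to detect, with full ground truth for recovery tests.

**Belief model.** Each participant × trial carries a latent logit vector
over the four options, starting at 0 (uniform). The contextually
supported sense (sense 2 if bias > 0.5, else sense 1) drifts at
`gain × ε` logit/s, where ε = 2·|bias − 0.5| is the bias extremity, and
receives an extra `word_boost` logit/s for `boost_duration` s after the
ambiguous word's onset; the other three logits perform a small Gaussian
random walk (`logit_jitter_sd`, 0.05 logit/√s). Probabilities are the
temperature-τ softmax. This linear-drift-plus-softmax process is the
simplest mechanism reproducing the three signatures the analysis
targets: gradual entropy decline, an onset-locked drop, and near-linear
scaling of the reduction rate with ε.

**Calibration.** Defaults were set from the softmax-entropy arithmetic:
with sentences of 6–9 s plus a 5 s tail, `drift_gain = 0.21` logit/s
puts the post-sentence target logit between ~1.3 (ε = 0.2) and ~3.4
(ε = 1), the stretch of the four-way softmax entropy curve that is
closest to linear, so ground-truth reduction rates span ≈ 0.008–0.037
bits/character with a closed-form second difference of ~1e-4 —
i.e. rates rise almost exactly linearly in ε, which is the planted
structure the linearity analyses should recover. `word_boost = 0.8`
logit/s for `boost_duration = 1` s produces a modest (~0.15–0.2 bit)
onset-locked drop; the boost is transient because a permanent rate
increase saturates every condition to H ≈ 0 and erases the bias-level
structure. Group entropy then runs from ≈ 1.9 bits (initial) to ≈ 0.4–1.4
bits (post-sentence, by ε), matching the scale on which the statistics
are meant to operate.

**Gaze model.** A fixation process redraws its target from the
instantaneous belief at exponentially spaced switch times (mean 0.3 s, a
conventional reading-fixation scale — per-sample redrawing would be
unrealistically fast). Gaze sits on the fixated option's rotating center
plus fixational drift noise: a stationary AR(1) (Ornstein–Uhlenbeck)
process with sd 0.8° and correlation time 5 s, so drift speeds stay far
below the 25°/s saccade threshold (white noise at 250 Hz would be
excluded wholesale by the velocity filter). Artifacts are planted
explicitly: `saccade_fraction` of samples is replaced by ~20 ms
ballistic runs at 80–300°/s, and `offscreen_fraction` moved outside the
screen.

**Design defaults** mirror the study design: 33 participants, six bias
levels {0, 0.2, 0.4, 0.6, 0.8, 1.0} (0.5 supported but excluded by
default), 30 trials per level, sentence lengths ~N(31, 3²) characters
(truncated ≥ 10), durations uniform 6–9 s, the ambiguous word's onset at
a uniform 30–70% of the sentence (never the first word). Word onsets
come from a synthetic segmentation into 1–3-character words with
characters spread uniformly in time, written to a forced-aligner-style
TSV. The sample rate defaults to 250 Hz, a stand-in for 1000 Hz hardware
that keeps desk-scale studies fast; it is configurable up. Per-trial
sentence durations are a plausible range, not measured values. All
randomness flows from one seed through named substreams (trials,
participant gains, belief, gaze), so any stage regenerates
independently and datasets rebuild byte-identically from their manifest.

**Linear schedule.** `entropy_schedule="linear"` replaces the drift
process by the deterministic belief whose ensemble entropy declines
exactly linearly from 2 bits to `linear_end_entropy` over the trial,
with no onset event. This is the calibration condition for the
permutation test: under it the pre/post contrast is constant in time, so
onset-locked rejections at α should occur at rate α. The drift schedule
cannot produce exact linearity, and under its sigmoid decline the
onset-locked contrast is not exchangeable with random timepoints.

## What the generator does and does not emulate

Passing tests show the pipeline recovers planted structure from data
with fixation persistence, saccade/off-screen artifacts, participant
heterogeneity and binomial sampling noise. They do not certify behaviour
on real eye-tracking data: the generator has no main-sequence saccade
dynamics, microsaccades, blinks, pupil signals, calibration drift,
smooth pursuit of the rotating options, or item-level lexical effects,
and its belief model is a convenience, not a cognitive claim.

One measurement property matters when reading small simulations: pooled
plug-in entropy is biased downward when few independent fixations land
in a bin, more so in high-entropy bins, which compresses early-vs-late
contrasts at small participant counts. The desk-scale studies therefore
use participant counts chosen so the planted effects dominate this bias;
the full 33-participant design behaves better still.

## Desk-scale study sizes

The simulation studies in `semgaze.experiments` (also run by
`scripts/acceptance.py`) use reduced problem sizes chosen as the
package's desk-scale defaults: type-I calibration with 200 datasets of
12 trials × 8 participants (linear schedule, 1000 permutation draws);
detection power with 50 datasets of 18 trials × 25 participants and a
planted boost of 2.0 logit/s — a clearly supra-threshold event, since at
18 trials the full-design default boost (a ~0.16 bit drop, detectable
with 180 trials) is genuinely under-powered and the study's question is
whether a present event is detected; linearity recovery with 50
experiments of 72 trials (12 per level) × 12 participants with
2000-draw bootstrap CIs; at this size the percentile CI's finite-sample
coverage sits near 93–94%, so the ≥90% empirical coverage check holds in
expectation but individual 50-experiment replications can land a point
or two either side of it. Breakpoint recovery under noise is stated as a mean over 20 noise
draws at the ~0.15 bit per-bin fluctuation measured on default-config
profiles, because a per-draw bound cannot hold for arbitrary noise.

## Numerical conventions and degenerate inputs

Bins are half-open `[k·w, (k+1)·w)`; the bin containing an onset is
`floor(onset/w)`. Entropy uses 0·log 0 = 0. A velocity filter on < 2
samples is skipped with a warning. Zero-variance paired differences make
Cohen's d undefined (reported as NaN); an all-equal design short-circuits
to F = 0, p = 1 rather than 0/0. The permutation and bootstrap p-values
use +1 conventions and so never return exactly 0. Piecewise fits drop
missing bins before the grid search; `candidate_stride` thins the
breakpoint grid for speed at a resolution cost. Projection coordinates
outside [0, 1] are clamped before folding. Derived seeds are kept below
2³¹.

## Known limitations

* Group-level entropy hides individual differences by construction.
* The event-locked test's calibration is exact under a linear decline;
  under strongly curved declines the onset position (mid-sentence)
  is not exchangeable with uniform timepoints, a property of the
  design rather than the implementation.
* Axis-aligned bounding boxes make choice assignment exactly
  rotation-equivariant only under half-turns; labels on a rotating ring
  drawn upright motivate the axis alignment.
* The piecewise fit's exhaustive search is O(bins²) per trial with
  default 3 segments; very long trials benefit from `candidate_stride`
  or 500 ms bins.
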