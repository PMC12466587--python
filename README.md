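# semgaze

Time-resolved semantic uncertainty from group gaze data.

## The problem

When listeners hear a sentence containing an ambiguous word, their
interpretation converges on one meaning gradually, as context
accumulates. `semgaze` quantifies that convergence for a
gaze-contingent choice paradigm: four candidate meanings (two senses of
the ambiguous word and two related distractors) rotate on a 10° ring at
5°/s while each participant fixates the meaning they currently prefer.
Pooling all participants' momentary gaze-indicated choices in 100 ms
bins gives a distribution p(x₁..x₄) per bin, and the group's semantic
uncertainty is its Shannon entropy

    H = − Σᵢ p(xᵢ) log₂ p(xᵢ)   ∈ [0, 2] bits,

2 bits when all four meanings are equally considered, 0 when the group
is unanimous. On top of these uncertainty profiles the package
implements the paradigm's inferential layer:

* segment comparisons (initial / late / post-sentence) with a
  trial-level repeated-measures ANOVA;
* an **event-locked permutation test**: is the drop across the 1 s
  windows around the ambiguous word's onset larger than the same
  contrast at 10,000 random timepoints, i.e. beyond the global decline?
* **uncertainty reduction rates** (initial − post, per sentence
  character) compared across six semantic-bias levels with one-way
  ANOVA + Tukey HSD, bootstrap second differences (ΔM) testing
  linearity of rate vs bias, piecewise-linear **turning point** fits,
  and a 3 × 6 mixed ANOVA;
* a model-side analogue for masked language models: the ambiguous
  word's contextual embedding is projected onto the axis between two
  reference sense embeddings, U = 1 − |2·clamp(t, 0, 1) − 1|, computed
  incrementally as the sentence is revealed character by character, and
  correlated with the human profiles.

Because raw data for this paradigm are not publicly distributable, the
package ships a first-class synthetic generator (`semgaze.synthetic`)
that plants the assumed structure — bias-proportional belief drift, a
word-onset disambiguation boost, fixation persistence, saccade and
off-screen artifacts — with full ground truth for parameter-recovery
testing. It is aimed at psycholinguists and cognitive scientists who
want to run, audit or extend this style of analysis.

## Worked example

```python
from semgaze import GeneratorConfig, simulate_dataset
from semgaze.pipeline import preprocess_dataset, build_profiles
from semgaze.experiments import dataset_profiles
from semgaze.stats import event_locked_test, permutation_null

config = GeneratorConfig(n_participants=25, n_trials_per_bias=3,
                         word_boost=2.0, seed=2)
trials, profiles, summaries = dataset_profiles(config)
event = event_locked_test(profiles, window=1.0)
perm = permutation_null(profiles, n_iter=2000, window=1.0, seed=2)
print(event.pre_mean, event.post_mean, event.t, perm.p_one_sided)
```

prints (see `examples/02_event_locked_test.py` for the narrated
version):

```
18 trials; mean uncertainty 1 s before onset: 1.883 bits, 1 s after: 1.645 bits
paired t(17) = 8.01, two-sided p = 3.6e-07, Cohen's d = 1.89
permutation null (2000 random-timepoint draws): one-sided p = 0.0005
```

Uncertainty averages 1.88 bits in the second before the ambiguous
word's onset and 1.65 bits in the second after; the permutation p says a
pre/post drop this large arises at random timepoints in well under 1% of
draws, so the onset itself — not just the global decline — reduces
uncertainty. The other scripts in `examples/` walk through profile
construction (`01`), bias-modulated convergence rates with the ΔM
linearity test (`03`), and the embedding-projection uncertainty series
(`04`); each prints its numbers with a line on what they mean.

A thin CLI covers the same ground from a shell:

```bash
semgaze simulate --out data/demo --seed 1 --participants 8 --trials-per-bias 2
semgaze validate data/demo
semgaze analyze --dataset data/demo --out results/demo --seed 1
semgaze report results/demo
```

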