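"""Embedding-projection uncertainty of an incremental language model.

The model-side analogue of the gaze entropy: two reference sense
embeddings span an axis; the ambiguous word's contextual embedding is
projected onto it, and uncertainty U is 1 at the midpoint, 0 at either
sense.  Revealing the sentence one character at a time (the rest masked)
yields an uncertainty series comparable to the human profile.  The
synthetic provider plants a word embedding that drifts from the midpoint
toward the supported sense as context accumulates — no model download
needed; a transformers-backed adapter implements the same contract for a
real masked LM.
"""

import numpy as np

from semgaze.embedding import (
    SyntheticEmbeddingProvider,
    build_sense_reference,
    compare_to_human,
    incremental_series,
)

provider = SyntheticEmbeddingProvider(seed=4, noise_sd=0.05, context_noise_sd=0.05)
refs = build_sense_reference(
    sense_a=[(f"#A example {i}", (0, 2)) for i in range(20)],
    sense_b=[(f"#B example {i}", (0, 2)) for i in range(20)],
    provider=provider,
)

sentence = "#B the river bank was steep"      # context supports sense B
series = incremental_series(sentence, span=(12, 16), refs=refs, provider=provider)

print("visible chars -> U (1 = equidistant from both senses, 0 = resolved)")
for k in (1, len(sentence) // 4, len(sentence) // 2, 3 * len(sentence) // 4, len(sentence)):
    print(f"  {k:3d} / {len(sentence)}   U = {series.uncertainty[k - 1]:.3f}")
print(f"\nmean U over the sentence: {series.uncertainty.mean():.3f}")
print("U starts near 1 (little context) and falls toward 0 as the masked")
print("context is revealed and the embedding approaches the supported sense.")
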