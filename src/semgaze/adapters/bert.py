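"""Masked-LM embedding backend (optional; requires the ``bert`` extra).

Wraps a character-tokenised Chinese BERT-family checkpoint (e.g.
RoBERTa-wwm-ext) behind the :class:`~semgaze.embedding.EmbeddingProvider`
contract: the sentence is tokenised per character, characters beyond the
visible prefix are replaced by the mask token (the ambiguous word's
characters stay visible), and the word embedding is the mean of its
characters' final-hidden-layer states.  When the tokenizer merges
characters into multi-character tokens, the span is mapped through the
tokenizer's offset mapping and every token overlapping the span is
pooled; this is the adapter's interpretation of "final hidden layer" for
merged tokens, and is documented rather than asserted against any ground
truth.

transformers and torch are imported lazily so the rest of the package
works without them.
"""

from __future__ import annotations

import numpy as np

Span = tuple[int, int]


class HuggingFaceMaskedLMProvider:
    """Contextual embeddings from a local/hub masked-LM checkpoint."""

    def __init__(self, model_name: str = "hfl/chinese-roberta-wwm-ext", device: str = "cpu") -> None:
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ImportError(
                "the masked-LM backend needs the 'bert' extra: pip install semgaze[bert]"
            ) from exc
        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name).to(device).eval()
        self.device = device
        self.dim = int(self.model.config.hidden_size)

    def _embed(self, chars: list[str], span: Span) -> np.ndarray:
        # feed the characters pre-split so mask substitution never shifts
        # the span; word_ids() maps tokens back to character positions
        torch = self._torch
        enc = self.tokenizer(chars, is_split_into_words=True, return_tensors="pt")
        word_ids = enc.word_ids(0)
        with torch.no_grad():
            out = self.model(**{k: v.to(self.device) for k, v in enc.items()})
        hidden = out.last_hidden_state[0].cpu().numpy()
        rows = [
            i
            for i, w in enumerate(word_ids)
            if w is not None and span[0] <= w < span[1]
        ]
        if not rows:
            raise ValueError(f"no tokens overlap span {span}")
        return hidden[rows].mean(axis=0)

    def embed_word_in_full_sentence(self, sentence: str, span: Span) -> np.ndarray:
        return self._embed(list(sentence), span)

    def embed_word_in_context(self, sentence: str, visible_len: int, span: Span) -> np.ndarray:
        mask = self.tokenizer.mask_token
        chars = [
            c if (i < visible_len or span[0] <= i < span[1]) else mask
            for i, c in enumerate(sentence)
        ]
        return self._embed(chars, span)
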