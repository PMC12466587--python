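"""Embedding-projection uncertainty of a masked language model.

The model-side analogue of the gaze entropy measure: for an ambiguous
word with two senses, two *reference sense embeddings* are built by
averaging contextual embeddings of the word over sense-annotated
sentences.  The word's embedding ``e`` in a partially revealed sentence
is projected onto the axis between the references,

    t = <e - ref_A, ref_B - ref_A> / ||ref_B - ref_A||^2,
    U = 1 - |2 * clamp(t, 0, 1) - 1|,

so U = 0 when the representation coincides with either sense, U = 1 at
the midpoint, linear in between; coordinates beyond a reference are
clamped before the folding.  Stepping the visible prefix one character at
a time (remaining characters masked, the ambiguous word always visible)
yields an incremental uncertainty series comparable to the human
profiles.

The pluggable provider contract keeps the analysis independent of any
model download: :class:`SyntheticEmbeddingProvider` plants a known
embedding trajectory for tests and simulations, and an optional
transformers-backed adapter lives in :mod:`semgaze.adapters.bert`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import stats as sps

from .entropy import UncertaintyProfile
from .synthetic import TrialSpec

__all__ = [
    "EmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "SenseReference",
    "ModelUncertaintySeries",
    "build_sense_reference",
    "projection_uncertainty",
    "incremental_series",
    "step_times",
    "CorrelationResult",
    "compare_to_human",
]

Span = tuple[int, int]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for contextual-embedding backends.

    Implementations must return vectors of a fixed dimension and be
    deterministic for fixed inputs.
    """

    dim: int

    def embed_word_in_context(self, sentence: str, visible_len: int, span: Span) -> np.ndarray:
        """Embedding of the word at ``span`` when only the first
        ``visible_len`` characters are revealed (the rest masked, the word
        itself always visible)."""
        ...

    def embed_word_in_full_sentence(self, sentence: str, span: Span) -> np.ndarray:
        """Embedding of the word at ``span`` with the whole sentence visible."""
        ...


class SyntheticEmbeddingProvider:
    """Deterministic stand-in backend with a planted sense geometry.

    Two anchor vectors ``anchor_a`` and ``anchor_b`` (orthogonal, equal
    norm) span the sense axis.  Each sentence has a latent sense
    coordinate ``t* in [0, 1]`` given by ``sense_of`` (a callable or
    mapping; default: 1.0 if the sentence contains ``"#B"``, 0.0 if
    ``"#A"``, else 0.5).  The full-sentence embedding sits at ``t*`` on
    the axis plus isotropic noise of sd ``noise_sd``; the incremental
    embedding moves linearly from the midpoint (no context) to ``t*``
    (full context) as the visible prefix grows, plus noise of sd
    ``context_noise_sd``.  All noise is a deterministic function of
    (seed, sentence, step), so repeated calls are bit-identical.
    """

    def __init__(
        self,
        dim: int = 32,
        seed: int = 0,
        noise_sd: float = 0.05,
        context_noise_sd: float = 0.0,
        sense_of: Callable[[str], float] | Mapping[str, float] | None = None,
        scale: float = 1.0,
    ) -> None:
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self.noise_sd = noise_sd
        self.context_noise_sd = context_noise_sd
        self._sense_of = sense_of
        rng = np.random.default_rng([seed, 0])
        a = rng.normal(size=dim)
        b = rng.normal(size=dim)
        b -= a @ b / (a @ a) * a
        self.anchor_a = scale * a / np.linalg.norm(a)
        self.anchor_b = scale * b / np.linalg.norm(b)

    def sense_target(self, sentence: str) -> float:
        if self._sense_of is None:
            if "#B" in sentence:
                return 1.0
            if "#A" in sentence:
                return 0.0
            return 0.5
        if isinstance(self._sense_of, Mapping):
            return float(self._sense_of.get(sentence, 0.5))
        return float(self._sense_of(sentence))

    def _noise(self, sentence: str, step: int, sd: float) -> np.ndarray:
        # step -1 encodes the full-sentence embedding
        if sd == 0:
            return np.zeros(self.dim)
        key = zlib.crc32(sentence.encode("utf-8"))
        rng = np.random.default_rng([self.seed, 1, key, step + 1])
        return rng.normal(0.0, sd, size=self.dim)

    def _point(self, t: float) -> np.ndarray:
        return self.anchor_a + t * (self.anchor_b - self.anchor_a)

    def embed_word_in_full_sentence(self, sentence: str, span: Span) -> np.ndarray:
        t_star = self.sense_target(sentence)
        return self._point(t_star) + self._noise(sentence, -1, self.noise_sd)

    def embed_word_in_context(self, sentence: str, visible_len: int, span: Span) -> np.ndarray:
        if not 0 <= visible_len <= len(sentence):
            raise ValueError("visible_len outside the sentence")
        t_star = self.sense_target(sentence)
        frac = visible_len / len(sentence) if sentence else 1.0
        t_k = 0.5 + (t_star - 0.5) * frac
        return self._point(t_k) + self._noise(sentence, visible_len, self.context_noise_sd)


@dataclass(frozen=True)
class SenseReference:
    """Mean sense embeddings defining the projection axis."""

    ref_a: np.ndarray
    ref_b: np.ndarray
    n_a: int = 1
    n_b: int = 1

    def __post_init__(self) -> None:
        axis = np.asarray(self.ref_b) - np.asarray(self.ref_a)
        if float(axis @ axis) <= 0.0:
            raise ValueError("degenerate sense reference: ref_a == ref_b")


def build_sense_reference(
    sense_a: Sequence[tuple[str, Span]],
    sense_b: Sequence[tuple[str, Span]],
    provider: EmbeddingProvider,
) -> SenseReference:
    """Average full-sentence word embeddings over the annotated sentences
    of each sense."""
    if not sense_a or not sense_b:
        raise ValueError("need at least one annotated sentence per sense")
    ea = np.mean([provider.embed_word_in_full_sentence(s, sp) for s, sp in sense_a], axis=0)
    eb = np.mean([provider.embed_word_in_full_sentence(s, sp) for s, sp in sense_b], axis=0)
    return SenseReference(ea, eb, len(sense_a), len(sense_b))


def projection_uncertainty(e: np.ndarray, refs: SenseReference) -> tuple[float, float]:
    """Normalized axis coordinate ``t`` and uncertainty ``U`` of one
    embedding.  U = 0 at either reference, 1 at the midpoint; components
    orthogonal to the axis do not contribute."""
    axis = np.asarray(refs.ref_b, dtype=float) - np.asarray(refs.ref_a, dtype=float)
    denom = float(axis @ axis)
    if denom <= 0.0:
        raise ValueError("zero-norm projection axis")
    t = float((np.asarray(e, dtype=float) - refs.ref_a) @ axis) / denom
    u = 1.0 - abs(2.0 * np.clip(t, 0.0, 1.0) - 1.0)
    return t, float(u)


@dataclass(frozen=True)
class ModelUncertaintySeries:
    """Per-step projection uncertainty over growing visible prefixes."""

    steps: np.ndarray       # visible prefix length, characters (1..L)
    t_coords: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        u = self.uncertainty
        if np.any(u < -1e-12) or np.any(u > 1.0 + 1e-12):
            raise ValueError("uncertainty must lie in [0, 1]")


def incremental_series(
    sentence: str,
    span: Span,
    refs: SenseReference,
    provider: EmbeddingProvider,
) -> ModelUncertaintySeries:
    """Uncertainty after each incremental character of context.

    For prefix length k = 1..len(sentence) the provider embeds the
    ambiguous word with characters <= k visible and the rest masked (the
    word itself always visible); the projection metric maps each embedding
    to U in [0, 1].
    """
    if not (0 <= span[0] < span[1] <= len(sentence)):
        raise ValueError("word span outside the sentence")
    steps = np.arange(1, len(sentence) + 1)
    ts, us = np.empty(len(steps)), np.empty(len(steps))
    for i, k in enumerate(steps):
        try:
            e = provider.embed_word_in_context(sentence, int(k), span)
        except Exception as exc:
            raise RuntimeError(f"embedding provider failed at step {k}") from exc
        ts[i], us[i] = projection_uncertainty(e, refs)
    return ModelUncertaintySeries(steps, ts, us)


def step_times(trial: TrialSpec) -> np.ndarray:
    """Map character steps 1..L to seconds via the word-onset timestamps.

    Characters within a word are spread uniformly between the word's onset
    and the next word's onset (sentence offset for the last word); the
    returned time of step k is the offset of the k-th character.
    """
    onsets = np.asarray([t for _, t in trial.word_onsets], dtype=float)
    lengths = np.asarray([len(w) for w in trial.words], dtype=float)
    char_starts = np.concatenate([[0.0], np.cumsum(lengths)])[:-1]
    bounds = np.concatenate([onsets, [trial.duration]])
    times = np.empty(trial.sentence_length)
    for w, (c0, ln) in enumerate(zip(char_starts, lengths)):
        t0, t1 = bounds[w], bounds[w + 1]
        for j in range(int(ln)):
            times[int(c0) + j] = t0 + (j + 1) / ln * (t1 - t0)
    return times


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int
    mode: str


def compare_to_human(
    model_series: Mapping[str, ModelUncertaintySeries],
    human_profiles: Mapping[str, UncertaintyProfile],
    trials: Mapping[str, TrialSpec] | None = None,
    mode: str = "per_trial_mean",
) -> CorrelationResult:
    """Pearson correlation between model and human uncertainty.

    ``per_trial_mean`` correlates one mean value per trial (df = trials -
    2).  ``resampled_concat`` maps model steps to seconds via the
    word-onset timestamps (``trials`` required), resamples the model
    series onto the human bin grid inside the sentence, concatenates all
    trials and correlates the pooled vectors (df = points - 2).
    """
    ids = sorted(set(model_series) & set(human_profiles))
    if mode == "per_trial_mean":
        if len(ids) < 3:
            raise ValueError("need >= 3 matching trials")
        x = np.array([model_series[i].uncertainty.mean() for i in ids])
        y = np.array([_nan_mean_sentence(human_profiles[i]) for i in ids])
    elif mode == "resampled_concat":
        if trials is None:
            raise ValueError("resampled_concat requires the trial specs")
        xs, ys = [], []
        for i in ids:
            prof, series = human_profiles[i], model_series[i]
            tt = step_times(trials[i])
            starts = prof.bin_starts
            grid = starts[starts < prof.duration] + prof.bin_width / 2.0
            h = prof.entropy[: len(grid)]
            u = np.interp(grid, tt, series.uncertainty)
            ok = np.isfinite(h)
            xs.append(u[ok])
            ys.append(h[ok])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(x) < 3:
            raise ValueError("fewer than 3 pooled points")
    else:
        raise ValueError("mode must be 'per_trial_mean' or 'resampled_concat'")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), df=len(x) - 2, p=float(p), n=len(x), mode=mode)


def _nan_mean_sentence(profile: UncertaintyProfile) -> float:
    h = profile.entropy[profile.bin_starts < profile.duration]
    h = h[np.isfinite(h)]
    return float(h.mean()) if h.size else float("nan")
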