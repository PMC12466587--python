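"""Group-level meaning distributions and Shannon-entropy uncertainty profiles.

Participants' per-sample meaning choices are pooled into half-open time
bins ``[k*w, (k+1)*w)`` tiling ``[0, D + tail)`` at 100 ms (default) or
500 ms resolution.  Within each bin the counts of samples assigned to each
of the four options are summed over all participants, and semantic
uncertainty is the base-2 Shannon entropy

    H = -sum_i p(x_i) log2 p(x_i),   0 <= H <= log2(4) = 2 bits,

of the pooled selection distribution.  Samples assigned to no option are
excluded from both numerator and denominator (the distribution is over the
four meanings only); bins with no assigned samples are *missing* — their
entropy is NaN and downstream averages skip them, rather than fabricating
a uniform fill.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .preprocess import ChoiceSeries
from .synthetic import TrialSpec

__all__ = [
    "MeaningDistribution",
    "UncertaintyProfile",
    "shannon_entropy",
    "bin_and_pool",
    "build_profile",
    "word_aligned_values",
]


@dataclass(frozen=True)
class MeaningDistribution:
    """Selection probabilities over the four options in one time bin."""

    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples > 0:
            p = np.asarray(self.p, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("p must be a non-negative 4-vector summing to 1")

    @property
    def missing(self) -> bool:
        return self.n_samples == 0


def shannon_entropy(d) -> float:
    """Base-2 Shannon entropy (bits) with the 0*log(0) = 0 convention.

    Accepts a :class:`MeaningDistribution` or a probability vector; returns
    NaN for a missing distribution.
    """
    if isinstance(d, MeaningDistribution):
        if d.missing:
            return float("nan")
        p = d.p
    else:
        p = np.asarray(d, dtype=float)
    return float(_scipy_entropy(p, base=2))


def _pool_counts(
    series_list: Sequence[ChoiceSeries], bin_width: float, t_end: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_bins = int(np.ceil(t_end / bin_width - 1e-9))
    counts = np.zeros((n_bins, 4), dtype=np.int64)
    for cs in series_list:
        m = (cs.choice >= 0) & (cs.times >= 0) & (cs.times < t_end)
        if not m.any():
            continue
        idx = np.floor(cs.times[m] / bin_width).astype(np.int64)
        np.minimum(idx, n_bins - 1, out=idx)
        counts += np.bincount(idx * 4 + cs.choice[m], minlength=n_bins * 4).reshape(n_bins, 4)
    bin_starts = np.arange(n_bins) * bin_width
    return counts, counts.sum(axis=1), bin_starts


def bin_and_pool(
    series_list: Sequence[ChoiceSeries], bin_width: float, t_end: float
) -> list[MeaningDistribution]:
    """Pool all participants' choices into per-bin meaning distributions."""
    counts, totals, _ = _pool_counts(series_list, bin_width, t_end)
    out = []
    for c, n in zip(counts, totals):
        if n == 0:
            out.append(MeaningDistribution(np.full(4, np.nan), 0))
        else:
            out.append(MeaningDistribution(c / n, int(n)))
    return out


@dataclass(frozen=True)
class UncertaintyProfile:
    """Time-resolved uncertainty profile of one trial.

    ``counts`` holds pooled per-bin, per-option sample counts; ``entropy``
    is NaN where a bin has no assigned samples.  ``word_onsets`` carries
    the onset time of every word of the sentence for word-aligned
    averaging; ``amb_onset`` is the ambiguous word's onset.
    """

    trial_id: str
    bias_level: float
    bin_width: float
    duration: float
    t_end: float
    counts: np.ndarray            # (n_bins, 4)
    word_onsets: np.ndarray
    amb_onset: float
    sentence_length: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.counts.shape[0]) * self.bin_width

    @property
    def n_samples(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        n = self.n_samples.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / n[:, None]
        p[n == 0] = np.nan
        return p

    @property
    def entropy(self) -> np.ndarray:
        p = self.probabilities
        with np.errstate(invalid="ignore", divide="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        h[self.n_samples == 0] = np.nan
        return h

    def distribution(self, k: int) -> MeaningDistribution:
        n = int(self.n_samples[k])
        if n == 0:
            return MeaningDistribution(np.full(4, np.nan), 0)
        return MeaningDistribution(self.counts[k] / n, n)

    def rebin(self, factor: int) -> "UncertaintyProfile":
        """Pool counts of ``factor`` consecutive bins (e.g. 100 ms -> 500 ms)."""
        n_bins = self.counts.shape[0]
        n_out = int(np.ceil(n_bins / factor))
        padded = np.zeros((n_out * factor, 4), dtype=self.counts.dtype)
        padded[:n_bins] = self.counts
        pooled = padded.reshape(n_out, factor, 4).sum(axis=1)
        return replace(self, counts=pooled, bin_width=self.bin_width * factor)

    def bin_of(self, t: float) -> int:
        return int(np.floor(t / self.bin_width))


def build_profile(
    trial: TrialSpec,
    series_list: Sequence[ChoiceSeries],
    bin_width: float = 0.1,
) -> UncertaintyProfile:
    """Bin, pool and attach word onsets for one trial.

    Both 0.1 s and 0.5 s bin widths are supported (any positive width
    works; the two named resolutions mirror the analysis defaults).
    """
    if not series_list:
        raise ValueError("no participants")
    counts, _, _ = _pool_counts(series_list, bin_width, trial.t_end)
    return UncertaintyProfile(
        trial_id=trial.trial_id,
        bias_level=trial.bias_level,
        bin_width=bin_width,
        duration=trial.duration,
        t_end=trial.t_end,
        counts=counts,
        word_onsets=np.asarray([t for _, t in trial.word_onsets], dtype=float),
        amb_onset=trial.word_onset,
        sentence_length=trial.sentence_length,
    )


def word_aligned_values(
    profile: UncertaintyProfile, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Entropy at the bins containing word onsets inside ``window``.

    Word alignment uses the bin *containing* each onset (floor).  Missing
    bins yield NaN entries; the caller decides how to average.  An empty
    result means no onsets fall in the window.
    """
    t0, t1 = window if window is not None else (0.0, profile.duration)
    onsets = profile.word_onsets
    onsets = onsets[(onsets >= t0) & (onsets < t1)]
    if onsets.size == 0:
        return np.empty(0)
    h = profile.entropy
    bins = np.floor(onsets / profile.bin_width).astype(int)
    bins = bins[bins < len(h)]
    return h[bins]
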