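"""Synthetic gaze datasets with known ground truth.

The generator emulates a gaze-contingent semantic choice task: on each
trial a listener hears a sentence containing an ambiguous word while four
candidate meanings (two senses, two related distractors) rotate on a 10
degree ring at 5 deg/s, and indicates the currently preferred meaning by
fixating it.  The statistical structure the downstream analysis assumes is
planted explicitly:

* a latent *belief* over the four options follows a logit-drift process —
  the contextually supported sense's logit grows linearly at a rate
  proportional to the bias extremity ``eps = 2*|bias - 0.5|``, with a
  transient extra boost after the ambiguous word's onset;
* gaze fixates the option drawn from the belief at exponentially spaced
  switch times, with isotropic position noise;
* a configurable fraction of samples is corrupted by high-velocity
  saccade segments and off-screen excursions.

Every random draw flows from one integer seed through named substreams so
that layouts, beliefs, gaze and artifacts are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import softmax

__all__ = [
    "ROLES",
    "GeneratorConfig",
    "OptionLayout",
    "TrialSpec",
    "BeliefTrajectory",
    "GazeRecording",
    "SyntheticDataset",
    "simulate_belief",
    "sample_gaze",
    "simulate_trials",
    "simulate_dataset",
    "generate_dataset",
    "load_dataset",
    "drift_logits",
    "ensemble_entropy_closed_form",
    "entropy_four_way",
    "invert_entropy_to_ptarget",
]

#: fixed role of each option index
ROLES = ("sense1", "sense2", "distractor1", "distractor2")
SENSE1, SENSE2 = 0, 1

_ALPHABET = np.array(list("abcdefghijklmnopqrstuvwxyz"))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Defaults follow the task design: 33 participants, six semantic bias
    levels, 180 trials at 30 per level, sentences of ~31 characters lasting
    6-9 s, the ambiguous word onset at 30-70% of the sentence.  The sample
    rate defaults to 250 Hz (a configurable stand-in for 1000 Hz hardware).

    Drift parameters are in logit units per second: ``drift_gain`` scales
    with bias extremity, ``word_boost`` acts only for ``boost_duration``
    seconds after the ambiguous word's onset.  ``entropy_schedule`` may be
    set to ``"linear"`` to plant an exactly linear ensemble-entropy decline
    with no word-onset event (the calibration condition for the
    event-locked permutation test).
    """

    n_participants: int = 33
    n_trials_per_bias: int = 30
    bias_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    sample_rate: float = 250.0
    sentence_duration: tuple[float, float] = (6.0, 9.0)
    word_onset_fraction: tuple[float, float] = (0.3, 0.7)
    sentence_length_mean: float = 31.0
    sentence_length_sd: float = 3.0
    sentence_length_min: int = 10
    drift_gain: float = 0.21
    word_boost: float = 0.8
    boost_duration: float = 1.0
    softmax_temperature: float = 1.0
    logit_jitter_sd: float = 0.05
    participant_gain_sd: float = 0.15
    fixation_mean: float = 0.3
    gaze_noise_sd: float = 0.8
    noise_tau: float = 5.0
    saccade_fraction: float = 0.05
    offscreen_fraction: float = 0.02
    post_tail: float = 5.0
    entropy_schedule: str = "drift"
    linear_end_entropy: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= b <= 1.0 for b in self.bias_levels):
            raise ValueError("bias levels must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax temperature must be positive")
        lo, hi = self.word_onset_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("word onset fraction range must lie in (0, 1)")
        if self.entropy_schedule not in ("drift", "linear"):
            raise ValueError("entropy_schedule must be 'drift' or 'linear'")
        for name in ("fixation_mean", "boost_duration", "post_tail"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("saccade_fraction", "offscreen_fraction"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class OptionLayout:
    """Geometry of the four rotating meaning options.

    The options occupy four of five equidistant positions on a ring of
    ``radius`` degrees and rotate rigidly at ``rotation_speed`` deg/s in
    ``direction`` (+1 counterclockwise, -1 clockwise).  ``label_lengths``
    are the option label lengths in characters, which set bounding-box
    widths downstream.
    """

    base_angles: tuple[float, float, float, float]
    label_lengths: tuple[int, int, int, int]
    direction: int = 1
    radius: float = 10.0
    rotation_speed: float = 5.0
    char_size: float = 1.2

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if len(self.base_angles) != 4 or len(self.label_lengths) != 4:
            raise ValueError("layout needs exactly 4 options")
        # base angles must be 4 distinct members of {theta0 + k*72}
        rel = (np.asarray(self.base_angles) - self.base_angles[0]) % 360.0
        steps = np.round(rel / 72.0)
        if not np.allclose(rel, steps * 72.0, atol=1e-6) or len(set(steps)) != 4:
            raise ValueError("base_angles must occupy 4 distinct positions on the 72-degree grid")

    def angles_at(self, t) -> np.ndarray:
        """Option angles (degrees) at time(s) ``t``; shape ``t.shape + (4,)``."""
        t = np.asarray(t, dtype=float)
        base = np.asarray(self.base_angles, dtype=float)
        return (base + self.direction * self.rotation_speed * t[..., None]) % 360.0

    def centers_at(self, t) -> np.ndarray:
        """Option center coordinates (degrees) at time(s) ``t``; shape ``t.shape + (4, 2)``."""
        ang = np.deg2rad(self.angles_at(t))
        return self.radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)


@dataclass(frozen=True)
class TrialSpec:
    """One sentence trial: bias level, timing, word onsets and layout."""

    trial_id: str
    word_id: str
    bias_level: float
    duration: float               # audio sentence duration D, seconds
    sentence_length: int          # characters
    word_onset: float             # ambiguous word onset, seconds from sentence onset
    word_offset: float
    word_onsets: tuple[tuple[int, float], ...]   # (word index, onset) for all words
    words: tuple[str, ...]
    layout: OptionLayout
    option_labels: tuple[str, str, str, str]
    post_tail: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias_level <= 1.0:
            raise ValueError("bias level must lie in [0, 1]")
        if not 0.0 < self.word_onset < self.duration:
            raise ValueError("ambiguous word onset must lie strictly inside (0, duration)")
        onsets = [t for _, t in self.word_onsets]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("word onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.duration):
            raise ValueError("word onsets must lie in [0, duration)")
        if len(self.option_labels) != 4:
            raise ValueError("need exactly 4 option labels")

    @property
    def extremity(self) -> float:
        """Bias extremity eps = 2*|b - 0.5| in [0, 1]."""
        return 2.0 * abs(self.bias_level - 0.5)

    @property
    def target_option(self) -> int:
        """Contextually supported sense: sense2 if b > 0.5 else sense1."""
        return SENSE2 if self.bias_level > 0.5 else SENSE1

    @property
    def t_end(self) -> float:
        return self.duration + self.post_tail

    @property
    def sentence(self) -> str:
        return "".join(self.words)


@dataclass
class BeliefTrajectory:
    """Latent per-sample belief over the four options (rows sum to 1)."""

    times: np.ndarray
    probabilities: np.ndarray      # (T, 4)
    target_option: int

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] != len(self.times):
            raise ValueError("probabilities must have shape (len(times), 4)")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability vector must be non-negative and sum to 1")

    def at(self, t: float) -> np.ndarray:
        i = min(np.searchsorted(self.times, t, side="right") - 1, len(self.times) - 1)
        return self.probabilities[max(i, 0)]


@dataclass
class GazeRecording:
    """One participant's gaze stream for one trial, with generative truth.

    ``fixation_target`` is the option the latent fixation process was on at
    each sample; ``artifact`` marks samples replaced by saccade (1) or
    off-screen (2) corruption, for which the gaze position no longer
    reflects the fixation target.
    """

    samples: pd.DataFrame          # time_s, x_deg, y_deg, eye, valid
    fixation_target: np.ndarray    # (T,) int
    artifact: np.ndarray           # (T,) int: 0 clean, 1 saccade, 2 off-screen


# ---------------------------------------------------------------------------
# entropy arithmetic shared with the oracle checks


def entropy_four_way(p_target) -> np.ndarray:
    """Entropy (bits) of (p, r, r, r) with r = (1-p)/3."""
    p = np.asarray(p_target, dtype=float)
    q = (1.0 - p) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0) - 3.0 * np.where(q > 0, q * np.log2(q), 0.0)
    return h


_P_GRID = np.linspace(0.25, 1.0 - 1e-12, 4096)
_H_GRID = entropy_four_way(_P_GRID)


def invert_entropy_to_ptarget(h) -> np.ndarray:
    """Target probability p >= 1/4 such that entropy_four_way(p) = h."""
    h = np.clip(np.asarray(h, dtype=float), 0.0, 2.0)
    # _H_GRID decreases in p; interpolate on the reversed grid
    return np.interp(h, _H_GRID[::-1], _P_GRID[::-1])


def drift_logits(trial: TrialSpec, gain: float, config: GeneratorConfig, times: np.ndarray) -> np.ndarray:
    """Deterministic target-logit path of the drift model (no jitter)."""
    eps = trial.extremity
    if not 0.0 <= eps <= 1.0:
        raise ValueError("bias extremity outside [0, 1]")
    boost = config.word_boost * np.clip(times - trial.word_onset, 0.0, config.boost_duration)
    return gain * eps * times + boost


def ensemble_entropy_closed_form(trial: TrialSpec, config: GeneratorConfig, times: np.ndarray) -> np.ndarray:
    """Closed-form ensemble entropy (bits) of the jitter-free belief."""
    if config.entropy_schedule == "linear":
        return _linear_schedule(times, trial.t_end, config.linear_end_entropy)
    x = drift_logits(trial, config.drift_gain, config, times) / config.softmax_temperature
    p = np.exp(x) / (np.exp(x) + 3.0)
    return entropy_four_way(p)


def _linear_schedule(times: np.ndarray, t_end: float, h_end: float) -> np.ndarray:
    return 2.0 - (2.0 - h_end) * np.asarray(times) / t_end


# ---------------------------------------------------------------------------
# belief simulation


def simulate_belief(
    trial: TrialSpec,
    participant_gain: float,
    config: GeneratorConfig,
    rng=None,
) -> BeliefTrajectory:
    """Simulate the latent belief trajectory for one participant x trial.

    Under the default ``"drift"`` schedule all logits start at 0 (uniform
    belief); the target sense's logit grows at ``participant_gain * eps``
    before the ambiguous word's onset and gains an extra ``word_boost``
    rate for ``boost_duration`` seconds after it; the other three logits
    perform a small Gaussian random walk (sd ``logit_jitter_sd`` per
    sqrt-second).  Probabilities are the temperature-``tau`` softmax of the
    logits.

    Under the ``"linear"`` schedule the belief is the deterministic
    distribution whose entropy declines linearly from 2 bits to
    ``linear_end_entropy`` over the trial; there is no word-onset event.
    """
    if not np.isfinite(participant_gain):
        raise ValueError("participant_gain must be finite")
    rng = _as_rng(rng if rng is not None else config.seed)
    n = int(round(trial.t_end * config.sample_rate))
    times = np.arange(n) / config.sample_rate

    if config.entropy_schedule == "linear":
        p_t = invert_entropy_to_ptarget(_linear_schedule(times, trial.t_end, config.linear_end_entropy))
        probs = np.full((n, 4), 0.0)
        probs[:, :] = ((1.0 - p_t) / 3.0)[:, None]
        probs[:, trial.target_option] = p_t
        return BeliefTrajectory(times, probs, trial.target_option)

    logits = np.zeros((n, 4))
    logits[:, trial.target_option] = drift_logits(trial, participant_gain, config, times)
    others = [i for i in range(4) if i != trial.target_option]
    if config.logit_jitter_sd > 0:
        dt = 1.0 / config.sample_rate
        steps = rng.normal(0.0, config.logit_jitter_sd * np.sqrt(dt), size=(n, 3))
        steps[0] = 0.0
        logits[:, others] += np.cumsum(steps, axis=0)
    probs = softmax(logits / config.softmax_temperature, axis=1)
    return BeliefTrajectory(times, probs, trial.target_option)


# ---------------------------------------------------------------------------
# gaze sampling

#: saccade run length in samples at 250 Hz scales as ~20 ms of travel
_SACCADE_MS = 20.0


def sample_gaze(
    belief: BeliefTrajectory,
    layout: OptionLayout,
    config: GeneratorConfig,
    rng=None,
    screen_half=(19.8, 12.7),
) -> GazeRecording:
    """Render a gaze stream from a belief trajectory.

    A fixation target is redrawn from the instantaneous belief at
    exponentially spaced switch times (mean ``fixation_mean`` s); gaze sits
    on the current option's rotating center plus isotropic Gaussian noise.
    ``saccade_fraction`` of samples is then replaced by high-velocity
    (> 25 deg/s) ballistic segments and ``offscreen_fraction`` moved
    outside the screen area.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    times = belief.times
    n = len(times)
    t_end = times[-1] + 1.0 / config.sample_rate

    # -- fixation switch process
    n_seg_guess = max(8, int(t_end / max(config.fixation_mean, 1e-6) * 2) + 8)
    gaps = rng.exponential(config.fixation_mean, size=n_seg_guess) if config.fixation_mean > 0 else np.array([])
    switch_times = np.cumsum(gaps)
    while config.fixation_mean > 0 and (switch_times.size == 0 or switch_times[-1] < t_end):
        more = rng.exponential(config.fixation_mean, size=n_seg_guess)
        switch_times = np.concatenate([switch_times, switch_times[-1] + np.cumsum(more)])
    switch_times = switch_times[switch_times < t_end]
    seg_starts = np.concatenate([[0], np.searchsorted(times, switch_times)])
    seg_starts = np.unique(seg_starts)
    seg_starts = seg_starts[seg_starts < n]

    cum = np.cumsum(belief.probabilities[seg_starts], axis=1)
    u = rng.random(len(seg_starts))
    seg_targets = np.minimum((u[:, None] > cum).sum(axis=1), 3)
    seg_lengths = np.diff(np.concatenate([seg_starts, [n]]))
    target = np.repeat(seg_targets, seg_lengths)

    # -- positions on the rotating ring
    ang = np.deg2rad(
        np.asarray(layout.base_angles)[target]
        + layout.direction * layout.rotation_speed * times
    )
    pos = layout.radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if config.gaze_noise_sd > 0:
        # slow fixational drift: stationary AR(1) with sd gaze_noise_sd and
        # correlation time noise_tau, so drift speeds stay far below the
        # 25 deg/s saccade threshold (white noise at 250 Hz would not)
        from scipy.signal import lfilter

        rho = float(np.exp(-1.0 / (config.sample_rate * config.noise_tau)))
        eta = rng.normal(size=(n, 2))
        drive = config.gaze_noise_sd * np.sqrt(1.0 - rho**2) * eta
        drive[0] = config.gaze_noise_sd * eta[0]       # stationary start
        pos = pos + lfilter([1.0], [1.0, -rho], drive, axis=0)

    artifact = np.zeros(n, dtype=np.int8)

    # -- saccade runs: ballistic motion > 25 deg/s replacing short windows
    if config.saccade_fraction > 0 and n > 10:
        run_len = max(2, int(round(_SACCADE_MS / 1000.0 * config.sample_rate)))
        n_runs = int(round(config.saccade_fraction * n / (run_len + 1)))
        starts = rng.choice(np.arange(1, n - run_len - 1), size=min(n_runs * 2, n - run_len - 2), replace=False)
        placed = 0
        occupied = np.zeros(n, dtype=bool)
        dt = 1.0 / config.sample_rate
        for s in starts:
            if placed >= n_runs:
                break
            if occupied[s - 1 : s + run_len + 1].any():
                continue
            speed = rng.uniform(80.0, 300.0)          # deg/s, well above threshold
            theta = rng.uniform(0.0, 2.0 * np.pi)
            step = speed * dt * np.array([np.cos(theta), np.sin(theta)])
            k = np.arange(1, run_len + 1)[:, None]
            pos[s : s + run_len] = pos[s - 1] + k * step
            occupied[s - 1 : s + run_len + 1] = True
            artifact[s : s + run_len] = 1
            placed += 1

    # -- off-screen excursions
    if config.offscreen_fraction > 0 and n > 0:
        clean = np.flatnonzero(artifact == 0)
        m = min(int(round(config.offscreen_fraction * n)), len(clean))
        idx = rng.choice(clean, size=m, replace=False)
        sign = rng.choice([-1.0, 1.0], size=m)
        pos[idx, 0] = sign * (screen_half[0] + rng.uniform(0.5, 3.0, size=m))
        pos[idx, 1] = rng.uniform(-screen_half[1], screen_half[1], size=m)
        artifact[idx] = 2

    samples = pd.DataFrame(
        {
            "time_s": times,
            "x_deg": pos[:, 0],
            "y_deg": pos[:, 1],
            "eye": "R",
            "valid": np.ones(n, dtype=np.int8),
        }
    )
    return GazeRecording(samples, target.astype(np.int16), artifact)


# ---------------------------------------------------------------------------
# trial specs and whole datasets


def _make_words(rng: np.random.Generator, n_chars: int) -> tuple[str, ...]:
    lengths: list[int] = []
    remaining = n_chars
    while remaining > 0:
        ln = int(rng.choice([1, 2, 2, 2, 3]))
        ln = min(ln, remaining)
        lengths.append(ln)
        remaining -= ln
    return tuple("".join(rng.choice(_ALPHABET, size=ln)) for ln in lengths)


def _make_layout(rng: np.random.Generator) -> OptionLayout:
    theta0 = float(rng.uniform(0.0, 72.0))
    slots = rng.choice(5, size=4, replace=False)
    base = tuple(float((theta0 + 72.0 * k) % 360.0) for k in slots)
    lengths = tuple(int(v) for v in rng.integers(2, 10, size=4))
    direction = int(rng.choice([-1, 1]))
    return OptionLayout(base_angles=base, label_lengths=lengths, direction=direction)


def simulate_trials(config: GeneratorConfig) -> list[TrialSpec]:
    """Draw the trial list: bias levels x n_trials_per_bias, with layouts."""
    rng = np.random.default_rng([config.seed, 0])
    trials: list[TrialSpec] = []
    idx = 0
    for bias in config.bias_levels:
        for _ in range(config.n_trials_per_bias):
            duration = float(rng.uniform(*config.sentence_duration))
            n_chars = max(
                config.sentence_length_min,
                int(round(rng.normal(config.sentence_length_mean, config.sentence_length_sd))),
            )
            words = _make_words(rng, n_chars)
            char_dur = duration / n_chars
            starts = np.concatenate([[0], np.cumsum([len(w) for w in words])[:-1]])
            onsets = starts * char_dur
            frac = rng.uniform(*config.word_onset_fraction)
            # ambiguous word: the word (other than the first) whose onset is
            # closest to the drawn fraction of the sentence
            cand = np.arange(1, len(words))
            amb = int(cand[np.argmin(np.abs(onsets[1:] - frac * duration))])
            layout = _make_layout(rng)
            labels = tuple(
                "".join(rng.choice(_ALPHABET, size=ln)) for ln in layout.label_lengths
            )
            trials.append(
                TrialSpec(
                    trial_id=f"t{idx:04d}",
                    word_id=f"w{idx % 16:02d}",
                    bias_level=float(bias),
                    duration=duration,
                    sentence_length=n_chars,
                    word_onset=float(onsets[amb]),
                    word_offset=float(onsets[amb] + len(words[amb]) * char_dur),
                    word_onsets=tuple((int(i), float(t)) for i, t in enumerate(onsets)),
                    words=words,
                    layout=layout,
                    option_labels=labels,
                    post_tail=config.post_tail,
                )
            )
            idx += 1
    return trials


def participant_gains(config: GeneratorConfig) -> np.ndarray:
    """Per-participant drift gains, lognormal around ``drift_gain``."""
    rng = np.random.default_rng([config.seed, 1])
    return config.drift_gain * np.exp(
        rng.normal(0.0, config.participant_gain_sd, size=config.n_participants)
    )


@dataclass
class SyntheticDataset:
    """In-memory dataset: trials plus per (trial, participant) recordings."""

    config: GeneratorConfig
    trials: list[TrialSpec]
    gains: np.ndarray
    recordings: dict[tuple[str, int], GazeRecording]
    beliefs: dict[tuple[str, int], BeliefTrajectory] | None = None

    @property
    def participants(self) -> range:
        return range(self.config.n_participants)

    def trial(self, trial_id: str) -> TrialSpec:
        return next(t for t in self.trials if t.trial_id == trial_id)


def _simulate_stream(trial, gain, config, pi):
    rng_b = np.random.default_rng([config.seed, 2, int(trial.trial_id[1:]), pi])
    rng_g = np.random.default_rng([config.seed, 3, int(trial.trial_id[1:]), pi])
    belief = simulate_belief(trial, gain, config, rng_b)
    rec = sample_gaze(belief, trial.layout, config, rng_g)
    return belief, rec


def simulate_dataset(config: GeneratorConfig, store_beliefs: bool = False) -> SyntheticDataset:
    """Simulate the full dataset in memory (use for desk-scale configs)."""
    trials = simulate_trials(config)
    gains = participant_gains(config)
    recordings: dict[tuple[str, int], GazeRecording] = {}
    beliefs: dict[tuple[str, int], BeliefTrajectory] = {}
    for trial in trials:
        for pi in range(config.n_participants):
            belief, rec = _simulate_stream(trial, gains[pi], config, pi)
            recordings[(trial.trial_id, pi)] = rec
            if store_beliefs:
                beliefs[(trial.trial_id, pi)] = belief
    return SyntheticDataset(config, trials, gains, recordings, beliefs if store_beliefs else None)


# ---------------------------------------------------------------------------
# on-disk layout


def _trial_record(t: TrialSpec) -> dict:
    d = asdict(t)
    d["layout"] = asdict(t.layout)
    return d


def _trial_from_record(d: dict) -> TrialSpec:
    layout = OptionLayout(
        base_angles=tuple(d["layout"]["base_angles"]),
        label_lengths=tuple(d["layout"]["label_lengths"]),
        direction=d["layout"]["direction"],
        radius=d["layout"]["radius"],
        rotation_speed=d["layout"]["rotation_speed"],
        char_size=d["layout"]["char_size"],
    )
    return TrialSpec(
        trial_id=d["trial_id"],
        word_id=d["word_id"],
        bias_level=d["bias_level"],
        duration=d["duration"],
        sentence_length=d["sentence_length"],
        word_onset=d["word_onset"],
        word_offset=d["word_offset"],
        word_onsets=tuple((int(i), float(t)) for i, t in d["word_onsets"]),
        words=tuple(d["words"]),
        layout=layout,
        option_labels=tuple(d["option_labels"]),
        post_tail=d.get("post_tail", 5.0),
    )


def generate_dataset(config: GeneratorConfig, root) -> dict:
    """Write a dataset to ``root``: trials.json, words.tsv, manifest.json,
    gaze/<trial>_p<participant>.csv and truth/<trial>_p<participant>.csv.

    Streams are simulated one at a time, so arbitrarily large configs write
    in bounded memory.  Returns the manifest dictionary.
    """
    root = Path(root)
    if root.exists() and any(root.joinpath(n).exists() for n in ("manifest.json",)):
        raise FileExistsError(f"{root} already contains a dataset manifest")
    (root / "gaze").mkdir(parents=True, exist_ok=True)
    (root / "truth").mkdir(parents=True, exist_ok=True)

    trials = simulate_trials(config)
    ids = [t.trial_id for t in trials]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial ids")
    gains = participant_gains(config)

    with open(root / "trials.json", "w") as fh:
        json.dump([_trial_record(t) for t in trials], fh, indent=1)

    with open(root / "words.tsv", "w") as fh:
        fh.write("trial_id\tword_index\tword\tonset_s\n")
        for t in trials:
            for (i, onset), w in zip(t.word_onsets, t.words):
                fh.write(f"{t.trial_id}\t{i}\t{w}\t{onset:.6f}\n")

    for trial in trials:
        for pi in range(config.n_participants):
            belief, rec = _simulate_stream(trial, gains[pi], config, pi)
            stem = f"{trial.trial_id}_p{pi:02d}.csv"
            rec.samples.to_csv(root / "gaze" / stem, index=False, float_format="%.5f")
            truth = pd.DataFrame(
                {
                    "time_s": belief.times,
                    "p0": belief.probabilities[:, 0],
                    "p1": belief.probabilities[:, 1],
                    "p2": belief.probabilities[:, 2],
                    "p3": belief.probabilities[:, 3],
                    "fixation_target": rec.fixation_target,
                    "artifact": rec.artifact,
                }
            )
            truth.to_csv(root / "truth" / stem, index=False, float_format="%.6f")

    manifest = {
        "format": "semgaze-dataset-v1",
        "seed": config.seed,
        "config": asdict(config),
        "n_trials": len(trials),
        "n_participants": config.n_participants,
        "participant_gains": [float(g) for g in gains],
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(root, load_truth: bool = False) -> SyntheticDataset:
    """Load a dataset written by :func:`generate_dataset`."""
    root = Path(root)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("bias_levels", "sentence_duration", "word_onset_fraction"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = GeneratorConfig(**cfg_dict)
    with open(root / "trials.json") as fh:
        trials = [_trial_from_record(d) for d in json.load(fh)]
    recordings: dict[tuple[str, int], GazeRecording] = {}
    for trial in trials:
        for pi in range(config.n_participants):
            stem = f"{trial.trial_id}_p{pi:02d}.csv"
            df = pd.read_csv(root / "gaze" / stem)
            target = np.full(len(df), -1, dtype=np.int16)
            artifact = np.zeros(len(df), dtype=np.int8)
            if load_truth and (root / "truth" / stem).exists():
                tr = pd.read_csv(root / "truth" / stem)
                target = tr["fixation_target"].to_numpy(dtype=np.int16)
                artifact = tr["artifact"].to_numpy(dtype=np.int8)
            recordings[(trial.trial_id, pi)] = GazeRecording(df, target, artifact)
    gains = np.asarray(manifest["participant_gains"], dtype=float)
    return SyntheticDataset(config, trials, gains, recordings)
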