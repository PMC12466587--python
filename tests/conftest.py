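import numpy as np
import pytest

from semgaze.synthetic import (
    GeneratorConfig,
    OptionLayout,
    TrialSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def layout() -> OptionLayout:
    return OptionLayout(
        base_angles=(0.0, 72.0, 144.0, 216.0),
        label_lengths=(4, 4, 4, 4),
        direction=1,
    )


def make_trial(
    bias: float = 0.0,
    duration: float = 8.0,
    onset: float = 4.0,
    n_chars: int = 32,
    layout: OptionLayout | None = None,
    trial_id: str = "t0000",
) -> TrialSpec:
    """Hand-built trial: 2-character words evenly spread over the audio."""
    layout = layout or OptionLayout(
        base_angles=(0.0, 72.0, 144.0, 216.0), label_lengths=(4, 4, 4, 4)
    )
    n_words = n_chars // 2
    onsets = tuple(
        (i, i * duration / n_words) for i in range(n_words)
    )
    return TrialSpec(
        trial_id=trial_id,
        word_id="w00",
        bias_level=bias,
        duration=duration,
        sentence_length=n_chars,
        word_onset=onset,
        word_offset=onset + 2 * duration / n_chars,
        word_onsets=onsets,
        words=tuple("ab" for _ in range(n_words)),
        layout=layout,
        option_labels=("aaaa", "bbbb", "cccc", "dddd"),
    )


@pytest.fixture
def trial(layout) -> TrialSpec:
    return make_trial(layout=layout)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(n_participants=4, n_trials_per_bias=1, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config, store_beliefs=True)


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Noise-free generator: gaze sits exactly on fixated option centers."""
    return GeneratorConfig(
        n_participants=2,
        n_trials_per_bias=1,
        gaze_noise_sd=0.0,
        saccade_fraction=0.0,
        offscreen_fraction=0.0,
        seed=11,
    )
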