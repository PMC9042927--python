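import numpy as np
import pytest

from wfmap import (SessionConfig, StimulusChannel, StimulusEvent,
                   synthesize_movie, tonotopy_sequence)
from wfmap.synthetic import GroundTruth


@pytest.fixture
def tone_channel() -> StimulusChannel:
    return tonotopy_sequence("up").to_channel(n_cycles=20)


@pytest.fixture
def single_channel_config() -> SessionConfig:
    """A 400 s green-light session with one 20 s-cycle channel at 5 fps."""
    ch = StimulusChannel("tones", 20.0, 20, events=[StimulusEvent(8.0, 4.0, 1.0)])
    return SessionConfig(530.0, 5.0, 400.0, [ch])


def make_truth(shape, label="tones", period=20.0, preferred=5.0, delay=4.0,
               amplitude_permille=1.0):
    """Uniform planted ground truth for a single channel."""
    return GroundTruth(
        preferred_time_s={label: np.full(shape, float(preferred))},
        amplitude={label: np.full(shape, amplitude_permille * 1e-3)},
        delay_s=np.full(shape, float(delay)),
    )


@pytest.fixture
def planted_movie(single_channel_config):
    truth = make_truth((4, 5))
    movie = synthesize_movie(truth, single_channel_config, noise_sd_permille=0.0)
    return movie, truth, single_channel_config
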