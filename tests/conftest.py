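import numpy as np
import pytest

from mcgkit.config import PipelineConfig
from mcgkit.preprocess import (
    AxisSegment,
    episode_axis_segments,
    preprocess_recording,
    segment_episodes,
)
from mcgkit.synthetic import SimulationConfig, generate_recording


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_normal_recording():
    """A low-noise 30 s NORMAL recording at 70 bpm, with its ground truth."""
    cfg = SimulationConfig.for_condition(
        "normal",
        30.0,
        hr_mean_bpm=70.0,
        seed=11,
        breathing_amplitude=0.01,
        noise_sd=0.005,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def normal_episode(clean_normal_recording):
    """First preprocessed episode of the clean NORMAL recording."""
    rec, _ = clean_normal_recording
    return segment_episodes(preprocess_recording(rec))[0]


@pytest.fixture(scope="session")
def normal_axis_segment(normal_episode):
    """AccX axis of the first preprocessed NORMAL episode."""
    return episode_axis_segments(normal_episode)[0]


@pytest.fixture
def random_segment():
    """A seeded random 10 s axis segment at 200 Hz."""
    rng = np.random.default_rng(314)
    return AxisSegment(
        samples=rng.standard_normal(2000),
        fs=200.0,
        axis="accx",
        episode_index=0,
        subject_id="rand",
    )
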