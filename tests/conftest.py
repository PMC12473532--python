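import numpy as np
import pytest

from mirrorvitals.signal_core import FaceObservation
from mirrorvitals.synthetic_scene import SceneConfig, generate_rgb_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free 60-s scene at 78 bpm."""
    return SceneConfig(fs=30.0, duration_s=60.0, hr_hz=1.3, noise_sd=0.0, seed=7)


@pytest.fixture
def clean_trace(clean_config):
    trace, _ = generate_rgb_trace(clean_config)
    return trace


@pytest.fixture
def full_face():
    return FaceObservation(box=(0, 0, 1, 1), confidence=1.0)
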