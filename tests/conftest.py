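import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    from myoflow.synth import SceneConfig
    return SceneConfig(image_shape=(128, 128), n_frames=11, seed=7,
                       noise_sd=4.0)
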