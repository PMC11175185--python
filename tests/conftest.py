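import numpy as np
import pytest

from emgfusion.preprocessing import Trial, WindowSpec
from emgfusion.synthetic import SyntheticConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """3 classes x 4 repetitions, short activations, fast to generate."""
    return SyntheticConfig(n_classes=3, n_repetitions=4, n_channels=4,
                           active_duration=2.0, rest_duration=1.0, seed=7)


@pytest.fixture
def small_recording(small_config):
    return generate_recording(small_config, subject_id=0)


@pytest.fixture
def random_trial(rng):
    return Trial(data=rng.standard_normal((500, 10)), label=1, repetition=1,
                 subject=0)


@pytest.fixture
def db1_window_spec():
    return WindowSpec.from_ms(200.0, fs=100.0, nt=500)
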