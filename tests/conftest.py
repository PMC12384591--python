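import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from eegcam import LabelScheme, NetworkSpec, PlantSpec, generate_dataset
from eegcam.nn import EmotionNet
from eegcam.preprocess import trials_to_arrays


@pytest.fixture(scope="session")
def small_plant():
    return PlantSpec(planted_channels=(19, 21), effect_size=2.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_plant):
    """8 trials (2 per quadrant) with signal planted on F4/FC6."""
    return generate_dataset(small_plant, 2)


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    """480 labelled quaternary windows from the small synthetic dataset."""
    X, y, windows = trials_to_arrays(small_dataset.trials, LabelScheme("quaternary"))
    return X, y


@pytest.fixture()
def tiny_spec():
    """Smallest topology-preserving spec on a reduced input grid, for fast unit tests."""
    return NetworkSpec.scaled(n_classes=2, width=1, input_shape=(16, 8), batch_size=32, epochs=2, dropout_keep=0.8)


@pytest.fixture()
def tiny_net(tiny_spec):
    return EmotionNet(tiny_spec, seed=0)


def tiny_windows(n=24, n_classes=2, seed=0, shape=(8, 16)):
    """Random windows (channels x time) with a class-dependent mean shift."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    X = rng.normal(size=(n, *shape))
    X += y[:, None, None] * 3.0
    return X, y
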