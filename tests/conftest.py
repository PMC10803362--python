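import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viadens.detect import DetectorConfig, train_detector
from viadens.synthdata import PatchSpec, render_patch

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def render_set(n, seed0, **spec_kwargs):
    """Easy synthetic patches: high-contrast nuclei, pale distractors."""
    return [
        render_patch(PatchSpec(seed=seed0 + i, **spec_kwargs)) for i in range(n)
    ]


@pytest.fixture(scope="session")
def easy_sets():
    """Train/val/test splits of easy 256x256 patches (fixed seeds)."""
    return {
        "train": render_set(24, 0),
        "val": render_set(8, 1000),
        "test": render_set(10, 2000),
    }


@pytest.fixture(scope="session")
def trained_model(easy_sets):
    """One detector trained on the easy set, shared across tests."""
    config = DetectorConfig(epochs=8, seed=7)
    return train_detector(easy_sets["train"], easy_sets["val"], config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
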