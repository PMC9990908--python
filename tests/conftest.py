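import numpy as np
import pytest

from embryoseg import (
    LabelVolume,
    ModelConfig,
    PhantomConfig,
    SegModel,
    VolumeImage,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One 48^3 phantom with 5 organs, shared across read-only tests."""
    cfg = PhantomConfig(shape=(48, 48, 48), n_organs=5, seed=11)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tiny_model_16():
    """Smallest legal network (16^3 input, patch 8) for plumbing tests."""
    cfg = ModelConfig.tiny(n_classes=4, input_size=16)
    return SegModel(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label_volume(rng, shape=(8, 8, 8), n_labels=3):
    return LabelVolume(rng.integers(0, n_labels + 1, size=shape))
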