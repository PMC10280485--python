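import numpy as np
import pytest

from vetgan import sgan
from vetgan.synthetic_data import SynthSpec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gradient_image():
    """16x16 RGB gradient covering a wide intensity range."""
    base = np.linspace(0, 255, 16, dtype=np.uint8)
    return np.broadcast_to(base[None, :, None], (16, 16, 3)).copy()


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic population shared by classifier tests."""
    return generate(SynthSpec(n_images=80, image_side=32, labeled_fraction=0.5, seed=42))


def tiny_sgan_config(**overrides):
    """Smallest sensible network for fast training smoke tests."""
    base = dict(
        image_side=32,
        latent_dim=8,
        generator_channels=(16, 12, 8, 8, 6),
        stage_channels=(4, 8),
        blocks_per_stage=(1, 1),
        interpretation_width=8,
        batch_size=16,
        max_epochs=2,
        patience=1,
    )
    base.update(overrides)
    return sgan.SGANConfig(**base)


@pytest.fixture()
def tiny_config():
    return tiny_sgan_config()
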