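import numpy as np
import pytest

from cyclesk.generator import GeneratorConfig
from cyclesk.losses import LossConfig
from cyclesk.trainer import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gen_cfg():
    """A generator small enough for sub-second forward passes."""
    return GeneratorConfig(channels=8, redcnn_layers=2, unet_layers=2,
                           reduction_dim=4)


@pytest.fixture
def small_train_cfg():
    return TrainConfig(lr_init=1e-3, lr_final=1e-4, decay_start_step=50,
                       decay_end_step=80, total_steps=100, seed=7,
                       checkpoint_every=0, input_size=32,
                       disc_base_channels=8)


@pytest.fixture
def small_loss_cfg():
    return LossConfig(vgg_width_factor=0.0625,
                      adversarial_form="least_squares")


@pytest.fixture
def pair_32(rng):
    x = rng.random((32, 32)).astype(np.float32)
    y = rng.random((32, 32)).astype(np.float32)
    return x, y
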