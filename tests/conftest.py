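import numpy as np
import pytest

import maskgan as mg
from maskgan.discriminator import BlockSpec, DiscriminatorConfig


@pytest.fixture(scope="session")
def phantom64():
    """One 64x64 phantom slice + lesion mask, shared across tests."""
    spec = mg.PhantomSpec().scaled(64)
    return mg.generate_phantom(spec)


@pytest.fixture(scope="session")
def spec64():
    return mg.PhantomSpec().scaled(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_gen_cfg():
    """16x16 generator for fast training-loop tests."""
    return mg.GeneratorConfig(input_size=16, depth=4, base_channels=4,
                              max_channels=16, dilation_blocks=2)


@pytest.fixture(scope="session")
def tiny_disc_cfg():
    """Six-block discriminator that fits a 16x16 input (4x4 output map)."""
    return DiscriminatorConfig(input_size=16, blocks=(
        BlockSpec(4, 2, 1, 4, "relu", batchnorm=False),
        BlockSpec(4, 2, 1, 8, "relu"),
        BlockSpec(3, 1, 1, 8, "relu"),
        BlockSpec(3, 1, 1, 8, "relu"),
        BlockSpec(3, 1, 1, 8, "relu"),
        BlockSpec(3, 1, 1, 1, "sigmoid", batchnorm=False),
    ))


@pytest.fixture(scope="session")
def phantom16():
    spec = mg.PhantomSpec().scaled(16)
    return mg.generate_phantom(spec)
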