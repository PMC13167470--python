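import numpy as np
import pytest

from chansplit.phantoms import ChannelStack, MixTask, NoiseSpec, generate_structure_channel


@pytest.fixture(scope="session")
def bars_and_spots():
    """Clean 2-channel filaments + puncta phantom, 256x256."""
    f = generate_structure_channel("filaments", (256, 256), 8e-4, 11)
    p = generate_structure_channel("puncta", (256, 256), 8e-4, 12)
    return ChannelStack(np.concatenate([f.data, p.data]),
                        channel_names=["filaments", "puncta"])


@pytest.fixture(scope="session")
def default_task():
    return MixTask(k=2, weights=[1.0, 1.0], mode="I",
                   noise=NoiseSpec(gaussian_sigma=8.0, poisson_scale=1.0, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
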