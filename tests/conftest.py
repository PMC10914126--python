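import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import halotile as ht

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def unet_d2():
    """Depth-2 toy U-Net (halo 8, F 2) — the fast exactness workhorse."""
    return ht.build_unet(2, base_channels=4)


@pytest.fixture(scope="session")
def unet_d2_weights(unet_d2):
    return ht.seeded_weights(unet_d2, 0)


@pytest.fixture(scope="session")
def unet_d3():
    """Depth-3 toy U-Net (per-conv halo 20, exact halo 24, F 4)."""
    return ht.build_unet(3, base_channels=2)


@pytest.fixture(scope="session")
def toy_densenet():
    """Growth-reduced FC-DenseNet replica with 3x3 transposed convs."""
    return ht.build_toy_densenet(n_pool=2, layers_per_block=1, growth=2,
                                 initial_channels=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
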