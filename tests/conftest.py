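import numpy as np
import pytest

from stainmap.io import default_cd_config, default_ppc_config
from stainmap.phantom import PhantomConfig, render_phantom_pair


# A small, quick phantom: 5x4 cells of 200 px, 3 gland clusters, one
# artifact cell. Session-scoped because rendering costs ~0.5 s.
SMALL_CONFIG = PhantomConfig(
    width_px=1000, height_px=800, n_glands=12, malignant_fraction=0.5,
    artifact_fraction=0.2, color_jitter_sd=0.0, rigid_offset=(12.0, -7.0, 1.5),
    seed=45,
)


@pytest.fixture(scope="session")
def noise_free_pair():
    return render_phantom_pair(SMALL_CONFIG)


@pytest.fixture(scope="session")
def noisy_pair():
    import dataclasses
    return render_phantom_pair(dataclasses.replace(SMALL_CONFIG, color_jitter_sd=0.02))


@pytest.fixture(scope="session")
def ppc_config():
    return default_ppc_config()


@pytest.fixture(scope="session")
def cd_config():
    return default_cd_config()
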