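import numpy as np
import pytest

from bamboocarbon.scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """Compact scene used across tests: 1.5 km extent, ~150 footprints."""
    return SceneConfig(extent=(0.0, 0.0, 1500.0, 1500.0), cell_size=25.0,
                       n_tracks=8, along_track_spacing=70.0, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
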