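import numpy as np
import pytest

from forestseg import (
    MultibandScene,
    SceneConfig,
    default_class_scheme,
    simulate_scene,
)


@pytest.fixture(scope="session")
def scheme():
    return default_class_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_scene(rng):
    """8×8 4-band random scene."""
    return MultibandScene(rng.uniform(0, 2047, size=(8, 8, 4)))


@pytest.fixture(scope="session")
def sim64():
    """One 64×64 simulated scene shared by read-only tests."""
    cfg = SceneConfig(height=64, width=64, rng_seed=7)
    scene, truth, training = simulate_scene(cfg)
    return scene, truth, training
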