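import numpy as np
import pytest

from lufor.scenes import CorruptionConfig, SceneConfig, default_classes, generate_scene


@pytest.fixture(scope="session")
def scene_128():
    """One deterministic 15-class scene used by several suites."""
    return generate_scene(SceneConfig(height=128, width=128, seed=7))


@pytest.fixture(scope="session")
def tiny_pools():
    """Minimal three-pool dataset (small scenes) for smoke training."""
    from lufor.scenes import generate_dataset

    return generate_dataset(
        6,
        SceneConfig(height=64, width=64, seed=3),
        CorruptionConfig(mislabel_fraction=0.2, drop_fraction=0.2, seed=3),
        annotated_fraction=0.5,
        test_fraction=0.5,
        seed=3,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
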