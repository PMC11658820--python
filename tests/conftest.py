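import numpy as np
import pytest

from sorghumnet import ArchConfig, SceneConfig, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene_cfg():
    """Scene config scaled down for fast tests (small canvas, few grains)."""
    return SceneConfig(
        canvas=(180, 96),
        total_range=(60, 240),
        total_mean=140.0,
        total_sigma=50.0,
        clutter=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_benchmark(tmp_path_factory):
    """Three synthetic panicle pairs on disk, shared across tests."""
    out = tmp_path_factory.mktemp("bench")
    cfg = SceneConfig(
        canvas=(180, 96),
        total_range=(60, 240),
        total_mean=140.0,
        total_sigma=50.0,
        clutter=0.3,
        seed=7,
    )
    manifest = generate_benchmark(cfg, n_panicles=3, out_dir=out, seed=7)
    return manifest


@pytest.fixture
def tiny_arch():
    """Smallest architecture that keeps the published topology (three
    columns, two pools, upsample x4, 2-channel head)."""
    return ArchConfig(
        input_size=(16, 16, 3),
        columns=(
            {"kernel_size": 3, "channel_dims": (2, 3, 2, 2)},
            {"kernel_size": 5, "channel_dims": (2, 2, 2, 1)},
            {"kernel_size": 7, "channel_dims": (1, 2, 1, 2)},
        ),
    )
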