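import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from wsirs.synthetic import SceneConfig, gen_scene


@pytest.fixture(scope="session")
def small_scene():
    """A modest deterministic scene: 2048x2048 canvas, 4 tiles."""
    cfg = SceneConfig(
        canvas_width=2048,
        canvas_height=2048,
        n_tumor_clusters=3,
        tumor_cells_per_cluster_mean=80,
        cluster_spread=90,
        til_density_background=30,
        seed=7,
    )
    return gen_scene(cfg)


@pytest.fixture(scope="session")
def feature_scene():
    """A larger scene guaranteed to have at least 10 tissue tiles."""
    cfg = SceneConfig(canvas_width=4096, canvas_height=4096, seed=11)
    return gen_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
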