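import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20110)


@pytest.fixture
def scene_dir(tmp_path):
    """Directory of three synthetic scenes with true counts 10/20/30."""
    from nucleocount import SceneSpec, generate_scene, write_scene

    for i, n in enumerate((10, 20, 30)):
        spec = SceneSpec.for_preset("5x", n_singlets=n, seed=100 + i)
        write_scene(generate_scene(spec), tmp_path / f"img_{i:03d}.tif", tmp_path / f"img_{i:03d}.json")
    return tmp_path
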