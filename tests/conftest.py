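import numpy as np
import pytest

from localcount import arch, synth


@pytest.fixture(scope="session")
def v2_spec():
    return arch.tasselnetv2_spec()


@pytest.fixture(scope="session")
def small_scene():
    """Deterministic 160x160 scene with 20 objects kept off the borders."""
    cfg = synth.SceneConfig(image_hw=(160, 160), count_range=(20, 20),
                            border_margin=64, blur_sigma_range=(0.0, 1.0))
    return synth.generate_scene(cfg, seed=3)


@pytest.fixture(scope="session")
def interior_scene():
    """464x464 scene whose smoothed object mass stays >= 64 px from borders
    (dot margin 80 = 64 plus the 16 px kernel truncation radius)."""
    cfg = synth.SceneConfig(image_hw=(464, 464), count_range=(100, 100),
                            border_margin=80, blur_sigma_range=(0.0, 1.0))
    return synth.generate_scene(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
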