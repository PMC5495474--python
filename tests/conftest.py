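import numpy as np
import pytest

from tubulequant import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One modest co-culture scene with its ground truth, shared read-only."""
    spec = SceneSpec(width_px=256, height_px=256, n_spheroids=3, n_tubule_nodes=8, seed=7)
    img, gt = generate_scene(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def clean_scene():
    """Noise- and texture-free scene: geometry and illumination only."""
    spec = SceneSpec(
        width_px=256, height_px=256, n_spheroids=3, n_tubule_nodes=8,
        noise_sd=0.0, cell_texture_sd=0.0, seed=11,
    )
    img, gt = generate_scene(spec)
    return spec, img, gt
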