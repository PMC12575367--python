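import numpy as np
import pytest

from radialign import scene


@pytest.fixture
def cfg():
    """Default scene: 512x512 px at 1.3 um/px, 300 um pillar, 1 min frames."""
    return scene.SceneConfig(seed=123)


@pytest.fixture
def small_cfg():
    """Small scene for rendering-heavy tests."""
    return scene.SceneConfig(seed=123, image_shape=(128, 128), pixel_size=1.0,
                             pillar_radius=50.0)


@pytest.fixture
def quadratic_field(cfg):
    return scene.generate_field(
        scene.FieldSpec(profile=scene.RadialProfile.quadratic(0.1, cfg.pillar_radius),
                        n_frames=5), cfg)


@pytest.fixture
def affine_field(cfg):
    return scene.generate_field(
        scene.FieldSpec(kind="affine", affine_matrix=np.diag([1.1, 1.1]),
                        n_frames=5), cfg)
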