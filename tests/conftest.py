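import numpy as np
import pytest

from eermetrics.synthetic import EyeSceneParams, generate_scene


def small_params(**overrides) -> EyeSceneParams:
    """Hand-checked 256 px scene: mildly droopy upper lid, centered iris."""
    base = dict(
        image_size=256,
        commissure_left=(24.0, 128.0),
        commissure_right=(232.0, 128.0),
        upper_apex_y=88.0,
        lower_apex_y=164.0,
        iris_center=(128.0, 128.0),
        iris_radius=44.0,
        pupil_radius=17.0,
        caruncle_radius=9.0,
        side="left",
        noise_sd=4.0,
        seed=0,
    )
    base.update(overrides)
    return EyeSceneParams(**base)


def unoccluded_params(**overrides) -> EyeSceneParams:
    """Both lid arcs verified to clear the iris disk entirely."""
    return small_params(
        upper_apex_y=80.0,
        lower_apex_y=176.0,
        iris_radius=30.0,
        pupil_radius=12.0,
        caruncle_radius=8.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def default_scene():
    """One default 512 px scene with its ground truth."""
    return generate_scene(EyeSceneParams(seed=1))


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_params(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
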