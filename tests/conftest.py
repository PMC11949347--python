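import numpy as np
import pytest

from wingflap import CameraRig, FlapConfig


@pytest.fixture
def small_rig() -> CameraRig:
    """Reduced-resolution rig with the study-style 90/30 fps timing."""
    return CameraRig(
        camera_height=250.0,
        depth_fps=90.0,
        rgb_fps=30.0,
        depth_resolution=(120, 160),
        rgb_resolution=(180, 320),
        board_side=60.0,
        pixel_pitch=0.8,
    )


@pytest.fixture
def tiny_rig() -> CameraRig:
    """Very coarse rig for fast end-to-end runs."""
    return CameraRig(
        camera_height=250.0,
        depth_fps=30.0,
        rgb_fps=10.0,
        depth_resolution=(40, 60),
        rgb_resolution=(60, 120),
        board_side=60.0,
        pixel_pitch=2.0,
    )


@pytest.fixture
def short_flap() -> FlapConfig:
    return FlapConfig(duration=0.5, noise_sigma=0.0, dropout_rate=0.0, seed=1)


def random_depth_frame(rng: np.random.Generator, shape=(30, 40),
                       invalid_fraction=0.05) -> np.ndarray:
    """Random scene depths in [150, 250] cm with some invalid pixels."""
    d = rng.uniform(150.0, 250.0, size=shape)
    d[rng.random(shape) < invalid_fraction] = 0.0
    return d
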