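import numpy as np
import pytest

from sidegait.background import build_background, foreground_mask, largest_silhouette
from sidegait.frontpose import calibrate
from sidegait.synthdepth import (FigureConfig, SceneConfig, render_front_pose,
                                 scene_depth, simulate_gugt)


@pytest.fixture(scope="session")
def scene_cfg():
    return SceneConfig()


@pytest.fixture(scope="session")
def figure():
    return FigureConfig()


@pytest.fixture(scope="session")
def clean_background(scene_cfg):
    return scene_depth(scene_cfg)


@pytest.fixture(scope="session")
def front_pose(scene_cfg, figure):
    """Noise-free calibration frame plus ground-truth joints."""
    return render_front_pose(scene_cfg, figure)


@pytest.fixture(scope="session")
def calibrated(front_pose, clean_background):
    frame, _ = front_pose
    return calibrate(frame, clean_background)


@pytest.fixture(scope="session")
def front_silhouette(front_pose, clean_background):
    frame, _ = front_pose
    return largest_silhouette(foreground_mask(frame, clean_background))


@pytest.fixture(scope="session")
def gugt_short(scene_cfg, figure):
    """Small noise-free GUGT run shared by the side-view tests."""
    return simulate_gugt(scene_cfg, figure, n_frames=40, seed=7)


def make_frame(value=3300, shape=(240, 320)):
    return np.full(shape, value, dtype=np.int32)
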