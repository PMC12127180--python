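import numpy as np
import pytest

from otokin.io_formats import LandmarkTrajectory
from otokin.synthetic_data import CanalPhantomConfig, simulate_canal


@pytest.fixture(scope="session")
def half_torus():
    """Constant-radius half torus, R=600 um, r=66 um, 3 um voxels."""
    cfg = CanalPhantomConfig(
        semi_axes=(600.0, 600.0), tube_radius=66.0, arc_span=180.0, voxel_size=3.0
    )
    return simulate_canal(cfg)


@pytest.fixture(scope="session")
def stenosis_torus():
    """Half torus with an ampulla bulge and a factor-0.5 pre-ampullary
    radial stenosis at 75% arclength."""
    cfg = CanalPhantomConfig(
        semi_axes=(600.0, 600.0),
        tube_radius=66.0,
        arc_span=180.0,
        voxel_size=3.0,
        ampulla_scale=1.5,
        stenosis=(0.75, 0.5),
    )
    return simulate_canal(cfg)


def yaw_trajectory(
    amplitude_deg: float, freq_hz: float, n_frames: int, fps: float = 30.0
) -> LandmarkTrajectory:
    """Stationary animal whose eye line yaws sinusoidally."""
    t = np.arange(n_frames) / fps
    yaw = np.deg2rad(amplitude_deg * np.sin(2 * np.pi * freq_hz * t))
    base = np.zeros((n_frames, 2))
    arm = 8.0  # px
    landmarks = {
        "body_com": base.copy(),
        "skull_center": base + [40.0, 0.0],
        "tail1": base - [40.0, 0.0],
        "tail2": base - [80.0, 0.0],
        "left_eye": np.stack(
            [50.0 - np.sin(yaw) * arm, np.cos(yaw) * arm], axis=1
        ),
        "right_eye": np.stack(
            [50.0 + np.sin(yaw) * arm, -np.cos(yaw) * arm], axis=1
        ),
    }
    return LandmarkTrajectory(fps, 0.1, landmarks)
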