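"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vbtcam.cli_io import PipelineConfig
from vbtcam.kinematics import LoadConfig
from vbtcam.reference_detection import detect_reference_corners
from vbtcam.synthetic_scene import (
    generate_motion_profile,
    make_default_scene,
    render_sequence,
)

settings.register_profile(
    "vbtcam", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("vbtcam")

#: small portrait frame for fast unit tests (~6.4 mm per pixel)
SMALL_SIZE = (270, 480)


@pytest.fixture(scope="session")
def small_scene():
    return make_default_scene(image_size=SMALL_SIZE, tilt_deg=10.0)


@pytest.fixture(scope="session")
def small_sequence(small_scene):
    profile = generate_motion_profile("constant", 0.35, 0.5, fps=60)
    return render_sequence(small_scene, profile)


@pytest.fixture(scope="session")
def small_config(small_scene):
    return PipelineConfig(geometry=small_scene.geometry, fps=60.0,
                          load=LoadConfig(m_athlete=80.0, m_load=20.0),
                          intrinsics=small_scene.intrinsics)


@pytest.fixture(scope="session")
def small_detection(small_sequence):
    """Reference corners + inlier polygons detected on the first frame."""
    corners, inliers = detect_reference_corners(small_sequence.frame(0))
    return corners, inliers


def random_pose(rng):
    """A valid camera pose: modest rotation, plane ~2 m in front."""
    angles = rng.uniform(-0.35, 0.35, size=3)

    def rot(axis, th):
        c, s = np.cos(th), np.sin(th)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = m[j, j] = c
        m[i, j], m[j, i] = -s, s
        return m

    R = rot(0, angles[0]) @ rot(1, angles[1]) @ rot(2, angles[2])
    t = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3),
                  rng.uniform(1.5, 3.0)])
    return R, t
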