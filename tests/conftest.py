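import numpy as np
import pytest

from trackgeom.camera_model import CameraParams, build_projection
from trackgeom.lane_detection import analyze_frame
from trackgeom.scene_model import TrackScene
from trackgeom.synthetic_data import (
    camera_looking_at,
    make_case,
    render_track,
)


@pytest.fixture(scope="session")
def scene():
    return TrackScene()


@pytest.fixture(scope="session")
def reference_camera():
    """A typical stands camera: pans 30 deg into the home stretch."""
    return CameraParams(
        azimuth=30.0, elevation=10.0, roll=0.0, fov=20.0,
        position=(0.0, -12.0, 6.0), image_size=(1280, 720),
    )


@pytest.fixture(scope="session")
def reference_projection(reference_camera):
    return build_projection(reference_camera)


@pytest.fixture(scope="session")
def truth_camera():
    """Ground-truth camera obeying the identifiability conventions
    (principal ray meets the ground at x = 0)."""
    return camera_looking_at((-40.0, -20.0, 8.0), (0.0, 4.5), 15.0)


@pytest.fixture(scope="session")
def rendered_frame(truth_camera, scene):
    """One rendered frame with its analytic truth (shared: rendering and
    detection dominate test runtime)."""
    return render_track(truth_camera, scene, seed=11)


@pytest.fixture(scope="session")
def detected(rendered_frame):
    lanes, vp = analyze_frame(rendered_frame["image"])
    return {"lanes": lanes, "vp": vp}


@pytest.fixture(scope="session")
def runner_case():
    """Noise-free runner fixture under a mid-stretch camera (no image)."""
    cam = camera_looking_at((-20.0, -25.0, 8.0), (0.0, 4.27), 12.0)
    return make_case(cam, n_frames=60, render_image=False, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
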