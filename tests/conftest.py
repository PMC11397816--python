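import numpy as np
import pytest

from canopykit import CameraIntrinsics, SceneConfig, generate_scene, render
from canopykit.synthetic import LabeledScene, PrimitiveKind, ScenePrimitive


@pytest.fixture(scope="session")
def K():
    """Round-number intrinsics: principal point on an exact pixel centre."""
    return CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=270.0,
                            width=640, height=540)


@pytest.fixture(scope="session")
def small_K():
    """Tiny frame for per-ray oracle checks."""
    return CameraIntrinsics(fx=40.0, fy=40.0, cx=16.0, cy=16.0,
                            width=32, height=32)


@pytest.fixture
def sphere_scene(K):
    """Single 50 mm sphere centred on the optical axis at 2 m, no noise."""
    sphere = ScenePrimitive(kind=PrimitiveKind.FRUIT_ELLIPSOID,
                            position=(0.0, 0.0, 2000.0),
                            dims=(50.0, 50.0, 50.0), instance_id=1)
    return LabeledScene(primitives=(sphere,), intrinsics=K,
                        resolution=(K.width, K.height), seed=0)


@pytest.fixture(scope="session")
def sizing_frames(K):
    """Ten 10-fruit unoccluded noiseless scenes at 2 m (100 fruit total)."""
    config = SceneConfig(n_fruit=10, n_branches=0, depth_range=(2000.0, 2000.0),
                         intrinsics=K)
    frames = []
    for seed in range(10):
        scene = generate_scene(config, seed=seed)
        frames.append((scene, render(scene, with_rgb=False)))
    return frames
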