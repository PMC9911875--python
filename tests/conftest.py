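import numpy as np
import pytest

from canopyrecon.synthetic import (
    SceneSpec,
    default_intrinsics,
    generate_scene,
    labeled_row_cloud,
    render_frame,
)


@pytest.fixture(scope="session")
def intr():
    """424x240 test-resolution intrinsics."""
    return default_intrinsics(424, 240)


@pytest.fixture(scope="session")
def two_plant_scene():
    return generate_scene(SceneSpec(n_plants=2, seed=7))


@pytest.fixture(scope="session")
def three_plant_scene():
    return generate_scene(SceneSpec(n_plants=3, seed=11))


@pytest.fixture(scope="session")
def rendered_frame(two_plant_scene, intr):
    scene, _ = two_plant_scene
    return render_frame(
        scene, [0.05, 0.0, 1.1], intr, rng=np.random.default_rng(42)
    )


@pytest.fixture(scope="session")
def sampled_cloud(two_plant_scene):
    """Directly sampled textured scene surface (soil + plants), ~25k points."""
    scene, _ = two_plant_scene
    cloud, labels = labeled_row_cloud(scene, density=2.0e4, seed=3)
    return cloud
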