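import numpy as np
import pytest
from hypothesis import settings

import binoseg as bs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_spec():
    return bs.SceneSpec(n_objects=6, category_count=8, floor_radius=3.5,
                        object_size_range=(0.5, 1.0))


@pytest.fixture(scope="session")
def small_rig():
    return bs.CameraRig(baseline=0.065, focal_length_px=72,
                        image_width=48, image_height=48)


@pytest.fixture(scope="session")
def small_frame(small_spec, small_rig):
    scene = bs.sample_scene(small_spec, seed=11)
    pose = bs.plan_camera_walk(small_spec, 1, seed=12)[0]
    return bs.render_stereo(scene, pose, small_rig)


@pytest.fixture(scope="session")
def tiny_net_config():
    """A miniature binocular network for fast structural tests."""
    return bs.NetworkConfig(input_height=16, input_width=16, class_count=5,
                            encoder_depth=2, seg_widths=(4, 6, 8),
                            depth_widths=(4, 6, 8), variant="binocular_full")


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, small_spec, small_rig):
    """A 2/1/1-scene dataset on disk, 2 frames per scene."""
    root = tmp_path_factory.mktemp("dataset")
    plan = bs.SplitPlan(train=2, val=1, test=1, frames_per_scene=2,
                        test_frames_per_scene=2)
    manifest = bs.generate_dataset(small_spec, small_rig, plan, root, seed=5)
    return root, manifest
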