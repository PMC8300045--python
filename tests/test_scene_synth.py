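"""Scene sampling, camera walks, ray-cast rendering and its ground truth."""

import math

import numpy as np
import pytest

import binoseg as bs
from binoseg.scene_synth import CameraPose, PlacedObject, SceneGraph


def _bare_scene(spec, objects, light=(0.0, 0.0, 1.0)):
    return SceneGraph(objects=tuple(objects), spec=spec,
                      dome_texture_seed=1, floor_texture_seed=2,
                      dome_color=np.array([0.5, 0.6, 0.8]),
                      floor_color=np.array([0.4, 0.4, 0.3]),
                      light_dir=np.asarray(light, dtype=float))


def _sphere(cat, pos, diameter=0.14):
    return PlacedObject("sphere", cat, np.asarray(pos, dtype=float), diameter,
                        0.0, texture_seed=7,
                        base_color=np.array([0.5, 0.5, 0.5]))


class TestSampleScene:
    def test_default_scene_places_distinct_objects_within_floor(self):
        spec = bs.SceneSpec()  # 24 objects, radius 5.2
        scene = bs.sample_scene(spec, seed=1)
        assert len(scene.objects) == 24
        cats = [o.category for o in scene.objects]
        assert len(set(cats)) == 24
        assert all(1 <= c <= spec.category_count for c in cats)
        for o in scene.objects:
            assert math.hypot(o.position[0], o.position[1]) <= spec.floor_radius

    def test_footprints_do_not_overlap(self, small_spec):
        scene = bs.sample_scene(small_spec, seed=3)
        obs = scene.objects
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                dist = math.hypot(*(obs[i].position[:2] - obs[j].position[:2]))
                assert dist > 0.9 * (obs[i].size + obs[j].size) / 2

    def test_empty_scene_renders_background_only(self, small_rig):
        spec = bs.SceneSpec(n_objects=0, category_count=4)
        scene = bs.sample_scene(spec, seed=2)
        pose = bs.plan_camera_walk(spec, 1, seed=2)[0]
        frame = bs.render_stereo(scene, pose, small_rig)
        assert set(np.unique(frame.left_labels)) == {0}
        assert set(np.unique(frame.right_labels)) == {0}

    def test_deterministic_for_fixed_seed(self, small_spec):
        a = bs.sample_scene(small_spec, seed=9)
        b = bs.sample_scene(small_spec, seed=9)
        for oa, ob in zip(a.objects, b.objects):
            assert oa.category == ob.category
            np.testing.assert_array_equal(oa.position, ob.position)
            assert oa.texture_seed == ob.texture_seed

    def test_more_objects_than_categories_is_an_error(self):
        with pytest.raises(ValueError, match="distinct"):
            bs.SceneSpec(n_objects=10, category_count=5).validate()

    def test_category_appearance_is_stable_across_scenes(self, small_spec):
        """A category is a fixed object: same shape, size, color and texture
        in every scene it appears in; only pose varies."""
        a = bs.sample_scene(small_spec, seed=1)
        b = bs.sample_scene(small_spec, seed=2)
        by_cat_a = {o.category: o for o in a.objects}
        by_cat_b = {o.category: o for o in b.objects}
        shared = set(by_cat_a) & set(by_cat_b)
        assert shared
        for cat in shared:
            oa, ob = by_cat_a[cat], by_cat_b[cat]
            assert oa.shape == ob.shape
            assert oa.size == ob.size
            assert oa.texture_seed == ob.texture_seed
            np.testing.assert_array_equal(oa.base_color, ob.base_color)


class TestCameraWalk:
    def test_frame_count_and_single_pose(self, small_spec):
        assert len(bs.plan_camera_walk(small_spec, 50, seed=0)) == 50
        assert len(bs.plan_camera_walk(small_spec, 1, seed=0)) == 1

    def test_nonpositive_frame_count_rejected(self, small_spec):
        with pytest.raises(ValueError):
            bs.plan_camera_walk(small_spec, 0, seed=0)

    def test_steps_bounded_and_poses_on_annulus_looking_inward(self, small_spec):
        max_step = 0.3
        poses = bs.plan_camera_walk(small_spec, 40, seed=4, max_step=max_step)
        for a, b in zip(poses[:-1], poses[1:]):
            assert np.linalg.norm(a.position - b.position) <= max_step + 1e-9
        for p in poses:
            r = math.hypot(p.position[0], p.position[1])
            assert small_spec.floor_radius <= r <= 1.1 * small_spec.floor_radius
            # looking inward: view direction points toward the scene axis
            to_center = -p.position[:2]
            assert np.dot(p.view_dir[:2], to_center) > 0

    def test_walk_deterministic(self, small_spec):
        a = bs.plan_camera_walk(small_spec, 10, seed=6)
        b = bs.plan_camera_walk(small_spec, 10, seed=6)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.position, pb.position)


class TestRenderGeometry:
    def test_disparity_matches_pinhole_closed_form(self):
        # point object at Z = 1.3 m, f = 200 px, B = 6.5 cm -> 10 px
        spec = bs.SceneSpec(n_objects=0, category_count=24)
        rig = bs.CameraRig(baseline=0.065, focal_length_px=200,
                           image_width=64, image_height=64)
        Z = 1.3
        scene = _bare_scene(spec, [_sphere(3, (0.0, 0.0, 1.1), 0.12)])
        pose = CameraPose(position=np.array([0.0, -Z, 1.1]),
                          view_dir=np.array([0.0, 1.0, 0.0]))
        frame = bs.render_stereo(scene, pose, rig)
        xs_l = np.nonzero(frame.left_labels == 3)[1].mean()
        xs_r = np.nonzero(frame.right_labels == 3)[1].mean()
        expected = 200 * 0.065 / Z
        assert abs((xs_l - xs_r) - expected) < 1.0

    def test_zero_baseline_gives_identical_eyes(self, small_spec):
        rig = bs.CameraRig(baseline=0.0, focal_length_px=72,
                           image_width=48, image_height=48)
        scene = bs.sample_scene(small_spec, seed=21)
        pose = bs.plan_camera_walk(small_spec, 1, seed=22)[0]
        frame = bs.render_stereo(scene, pose, rig)
        np.testing.assert_array_equal(frame.left_rgb, frame.right_rgb)
        np.testing.assert_array_equal(frame.left_labels, frame.right_labels)
        np.testing.assert_array_equal(frame.depth_left, frame.depth_right)

    def test_occlusion_nearest_surface_wins(self):
        spec = bs.SceneSpec(n_objects=0, category_count=24)
        rig = bs.CameraRig(baseline=0.0, focal_length_px=100,
                           image_width=32, image_height=32)
        near_obj = _sphere(1, (0.0, -0.5, 1.0), 0.3)
        far_obj = _sphere(2, (0.0, 0.5, 1.0), 0.3)
        scene = _bare_scene(spec, [near_obj, far_obj])
        pose = CameraPose(position=np.array([0.0, -2.0, 1.0]),
                          view_dir=np.array([0.0, 1.0, 0.0]))
        frame = bs.render_stereo(scene, pose, rig)
        assert (frame.left_labels == 1).any()
        # the farther object is completely hidden behind the nearer one
        assert not (frame.left_labels == 2).any()
        # and where the near object is seen, its depth is below the floor/dome
        m = frame.left_labels == 1
        assert frame.depth_left[m].max() < frame.depth_left[~m].min()

    def test_depth_monotone_along_shared_line_of_sight(self):
        spec = bs.SceneSpec(n_objects=0, category_count=24)
        rig = bs.CameraRig(baseline=0.0, focal_length_px=100,
                           image_width=32, image_height=32)
        a = _sphere(1, (0.0, -0.3, 1.0), 0.25)
        b = _sphere(2, (0.4, 0.8, 1.0), 0.8)
        scene = _bare_scene(spec, [a, b])
        pose = CameraPose(position=np.array([0.0, -2.0, 1.0]),
                          view_dir=np.array([0.0, 1.0, 0.0]))
        frame = bs.render_stereo(scene, pose, rig)
        da = frame.depth_left[frame.left_labels == 1]
        db = frame.depth_left[frame.left_labels == 2]
        assert da.size and db.size and da.max() < db.min()

    def test_camera_inside_object_is_degenerate(self, small_rig):
        spec = bs.SceneSpec(n_objects=0, category_count=24)
        scene = _bare_scene(spec, [_sphere(1, (0.0, -2.0, 1.0), 1.0)])
        pose = CameraPose(position=np.array([0.0, -2.0, 1.0]),
                          view_dir=np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            bs.render_stereo(scene, pose, small_rig)

    def test_render_deterministic(self, small_spec, small_rig):
        scene = bs.sample_scene(small_spec, seed=30)
        pose = bs.plan_camera_walk(small_spec, 1, seed=31)[0]
        f1 = bs.render_stereo(scene, pose, small_rig)
        f2 = bs.render_stereo(scene, pose, small_rig)
        np.testing.assert_array_equal(f1.left_rgb, f2.left_rgb)
        np.testing.assert_array_equal(f1.depth_right, f2.depth_right)


class TestNormalizeDepth:
    @pytest.mark.parametrize("raw,expected", [
        (2.0, 0.0),        # nearest plane
        (10.0, 1.0),       # farthest plane
        (6.0, 0.5),        # affine midpoint
        (0.5, 0.0),        # clipped below
        (99.0, 1.0),       # clipped above
    ])
    def test_affine_map(self, raw, expected):
        out = bs.normalize_depth(np.array([[raw]]), near=2.0, far=10.0)
        assert out[0, 0] == pytest.approx(expected)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            bs.normalize_depth(np.zeros((2, 2)), near=3.0, far=3.0)


class TestTextures:
    @pytest.mark.parametrize("exponent", [1.5, 2.0, 2.5])
    def test_power_spectrum_slope_matches_exponent(self, exponent):
        rng = np.random.default_rng(13)
        img = bs.powerlaw_texture((256, 256), exponent, rng)
        slope = bs.radial_power_slope(img)
        assert abs(slope + exponent) < 0.3

    def test_texture_range(self):
        img = bs.powerlaw_texture((64, 64), 2.0, np.random.default_rng(0))
        assert img.min() >= 0.0 and img.max() <= 1.0


def test_one_hot_round_trip(small_frame):
    labels = small_frame.left_labels
    one_hot = np.eye(9)[labels]
    assert (one_hot.sum(axis=-1) == 1).all()
    np.testing.assert_array_equal(one_hot.argmax(axis=-1), labels)
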