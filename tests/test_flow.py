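"""Preprocessing, Shi–Tomasi seeding, Lucas–Kanade tracking and feature rows."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.feature import corner_shi_tomasi

from flowskill.flow import (
    FlowRecord,
    LKParams,
    PointSet,
    Roi,
    build_feature_row,
    detect_initial_points,
    extract_features,
    feature_columns,
    preprocess_frame,
    track_step,
)

from conftest import roi_for


def checkerboard(square: int = 8, n: int = 8, lo: float = 0.1, hi: float = 0.9):
    tile = np.kron([[1, 0] * (n // 2), [0, 1] * (n // 2)] * (n // 2),
                   np.ones((square, square)))
    return lo + (hi - lo) * tile


class TestPreprocess:
    def test_output_is_binary_single_channel(self, two_tool_scene):
        out = preprocess_frame(two_tool_scene["frames"][0])
        assert out.ndim == 2
        assert set(np.unique(out)) <= {0, 255}

    def test_uniform_frame_gives_uniform_output(self):
        out = preprocess_frame(np.full((64, 64), 0.5))
        assert len(np.unique(out)) == 1

    def test_median_filter_removes_salt_and_pepper(self):
        """Isolated noise pixels vanish before thresholding with kernel 5."""
        rng = np.random.default_rng(0)
        frame = np.full((100, 100), 0.5)
        idx = rng.choice(10000, size=60, replace=False)
        frame.ravel()[idx] = 1.0  # isolated bright specks
        with_median = preprocess_frame(frame)
        from flowskill.flow import PreprocessParams

        no_median = preprocess_frame(frame, PreprocessParams(median_kernel=1))
        # without the median blur the specks survive thresholding as structure
        assert (no_median == 255).sum() < no_median.size
        assert (with_median == 255).all()  # uniform after denoising

    def test_binary_checkerboard_edges_preserved(self):
        binary = preprocess_frame(checkerboard())
        resp = corner_shi_tomasi(binary.astype(float))
        assert resp.max() > 0  # corner structure survives the chain

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.empty((0, 0)))

    def test_even_median_kernel_rejected(self):
        from flowskill.flow import PreprocessParams

        with pytest.raises(ValueError):
            preprocess_frame(np.ones((8, 8)), PreprocessParams(median_kernel=4))


class TestDetect:
    def test_uniform_roi_raises_shortfall_error(self):
        frame = np.full((80, 80), 0.5)
        with pytest.raises(ValueError, match="corners"):
            detect_initial_points(frame, Roi("left", 10, 10, 40, 40), n_points=5)

    def test_checkerboard_corners_near_square_intersections(self):
        """Detected corners lie within 1 px of true grid intersections."""
        sq = 8
        img = checkerboard(square=sq)
        roi = Roi("left", 4, 4, img.shape[1] - 8, img.shape[0] - 8)
        pts = detect_initial_points(img, roi, n_points=20, min_distance=3)
        # true intersections sit on pixel boundaries: k·sq − 0.5 in center coords
        shifted = pts.coords + 0.5
        offs = shifted - np.round(shifted / sq) * sq
        err = np.hypot(offs[:, 0], offs[:, 1])
        assert np.all(err <= 1.0 + 1e-9)

    def test_single_point_is_global_score_maximum(self):
        """n_points=1 returns the pixel a brute-force score scan selects."""
        img = np.zeros((60, 60))
        img[20:30, 25:35] = 1.0  # one bright square
        roi = Roi("left", 5, 5, 50, 50)
        pts = detect_initial_points(img, roi, n_points=1)
        resp = corner_shi_tomasi(img)
        interior = resp[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
        best = resp[int(pts.coords[0, 1]), int(pts.coords[0, 0])]
        assert best == pytest.approx(interior.max(), rel=1e-12)

    def test_points_respect_roi_containment(self, two_tool_scene):
        frames = two_tool_scene["frames"]
        scene = two_tool_scene["scene"]
        binary = preprocess_frame(frames[0])
        roi = Roi("left", *roi_for(two_tool_scene["traj_left"][0], scene.tool_radius,
                                   frames[0].shape))
        pts = detect_initial_points(binary, roi, 30)
        assert roi.contains(pts.coords).all()


class TestTrack:
    def _textured(self, seed=0, shape=(120, 160)):
        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.normal(0.5, 0.2, shape), 1.2)

    def test_identical_frames_give_zero_displacement(self):
        img = self._textured()
        pts = PointSet("left", np.array([[40.0, 50.0], [80.0, 60.0]]), np.ones(2, bool))
        new, disp = track_step(img, img, pts)
        assert np.allclose(disp, 0.0, atol=1e-6)
        assert new.status.all()

    def test_global_translation_recovered(self):
        """(3,0) px shift of a textured image → mean displacement ≈ (3,0)."""
        img = self._textured()
        shifted = np.roll(img, 3, axis=1)
        rng = np.random.default_rng(1)
        coords = np.stack([rng.uniform(30, 120, 30), rng.uniform(30, 90, 30)], axis=1)
        pts = PointSet("left", coords, np.ones(30, bool))
        _, disp = track_step(img, shifted, pts)
        assert np.linalg.norm(disp.mean(axis=0) - [3.0, 0.0]) < 0.5

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            track_step(np.zeros((10, 10)), np.zeros((12, 10)),
                       PointSet("left", np.zeros((1, 2)), np.ones(1, bool)))

    def test_point_leaving_frame_marked_lost(self):
        img = self._textured(shape=(60, 60))
        shifted = np.roll(img, -30, axis=1)  # content rushes out to the left
        pts = PointSet("left", np.array([[5.0, 30.0]]), np.ones(1, bool))
        new, _ = track_step(img, shifted, pts)
        assert not new.status.any()

    def test_featureless_window_marked_lost(self):
        flat = np.full((80, 80), 0.5)
        pts = PointSet("left", np.array([[40.0, 40.0]]), np.ones(1, bool))
        new, _ = track_step(flat, flat, pts)
        assert not new.status.any()  # structure tensor below min-eig threshold


class TestFeatureRow:
    def _record(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        prev_l, prev_r = rng.uniform(10, 50, (n, 2)), rng.uniform(60, 100, (n, 2))
        disp_l, disp_r = rng.normal(0, 1, (n, 2)), rng.normal(0, 1, (n, 2))
        return FlowRecord(
            frame_index=1,
            left=PointSet("left", prev_l + disp_l, np.ones(n, bool)),
            right=PointSet("right", prev_r + disp_r, np.ones(n, bool)),
            disp_left=disp_l,
            disp_right=disp_r,
        ), (prev_l, prev_r, disp_l, disp_r)

    def test_row_has_240_features(self):
        rec, _ = self._record()
        assert build_feature_row(rec).shape == (240,)
        assert len(feature_columns()) == 240

    def test_layout_and_displacement_oracle(self):
        """Row blocks are [L pos, L disp, R pos, R disp], each point-major."""
        rec, (pl, pr, dl, dr) = self._record()
        row = build_feature_row(rec)
        np.testing.assert_array_equal(row[0:60], (pl + dl).ravel())
        np.testing.assert_array_equal(row[60:120], dl.ravel())
        np.testing.assert_array_equal(row[120:180], (pr + dr).ravel())
        np.testing.assert_array_equal(row[180:240], dr.ravel())

    def test_zero_motion_row(self):
        rec, (pl, pr, _, _) = self._record()
        rec.disp_left = np.zeros_like(rec.disp_left)
        rec.disp_right = np.zeros_like(rec.disp_right)
        row = build_feature_row(rec)
        assert np.all(row[60:120] == 0) and np.all(row[180:240] == 0)

    def test_wrong_point_count_rejected(self):
        rec, _ = self._record(n=10)
        with pytest.raises(ValueError):
            build_feature_row(rec, n_points=30)


class TestExtract:
    def test_shapes_and_raw_buffer(self, two_tool_scene):
        frames = two_tool_scene["frames"]
        scene = two_tool_scene["scene"]
        shape = frames[0].shape
        fm = extract_features(
            frames,
            Roi("left", *roi_for(two_tool_scene["traj_left"][0], scene.tool_radius, shape)),
            Roi("right", *roi_for(two_tool_scene["traj_right"][0], scene.tool_radius, shape)),
        )
        assert fm.values.shape == (scene.n_frames - 1, 240)
        assert fm.raw.shape == (scene.n_frames, 30, 2, 2)

    def test_flow_position_consistency_bit_exact(self, two_tool_scene):
        """Stored displacement ≡ position difference, bit for bit, everywhere."""
        frames = two_tool_scene["frames"]
        scene = two_tool_scene["scene"]
        shape = frames[0].shape
        fm = extract_features(
            frames,
            Roi("left", *roi_for(two_tool_scene["traj_left"][0], scene.tool_radius, shape)),
            Roi("right", *roi_for(two_tool_scene["traj_right"][0], scene.tool_radius, shape)),
        )
        v = fm.values
        for pos_sl, disp_sl, tool in ((slice(0, 60), slice(60, 120), 0),
                                      (slice(120, 180), slice(180, 240), 1)):
            pos = v[:, pos_sl]
            disp = v[:, disp_sl]
            prev = np.vstack([fm.raw[0, :, tool, :].ravel(), pos[:-1]])
            np.testing.assert_array_equal(pos - prev, disp)

    def test_static_scene_zero_displacement(self):
        from flowskill.synth import SceneSpec, render_video

        sc = SceneSpec(n_frames=8, background_noise_sd=0.0, seed=0)
        still = np.tile([40.0, 60.0], (8, 1))
        frames, _ = render_video(still, still + [80.0, 0.0], sc)
        fm = extract_features(
            frames,
            Roi("left", *roi_for(still[0], sc.tool_radius, frames[0].shape)),
            Roi("right", *roi_for(still[0] + [80, 0], sc.tool_radius, frames[0].shape)),
        )
        assert np.all(fm.values[:, 60:120] == 0) and np.all(fm.values[:, 180:240] == 0)

    def test_rigid_translation_tracked_within_half_pixel(self):
        """Median LK displacement error ≤ 0.5 px over 50 translating frames."""
        from flowskill.synth import SceneSpec, render_video

        sc = SceneSpec(n_frames=51, seed=2)
        left = np.array([30.0, 40.0]) + np.outer(np.arange(51), [1.0, 1.0])
        right = np.array([110.0, 90.0]) + np.outer(np.arange(51), [0.5, -0.5])
        frames, _ = render_video(left, right, sc)
        fm = extract_features(
            frames,
            Roi("left", *roi_for(left[0], sc.tool_radius, frames[0].shape)),
            Roi("right", *roi_for(right[0], sc.tool_radius, frames[0].shape)),
        )
        err_l = np.abs(fm.values[:, 60:120].reshape(-1, 30, 2) - [1.0, 1.0])
        err_r = np.abs(fm.values[:, 180:240].reshape(-1, 30, 2) - [0.5, -0.5])
        assert np.median(err_l) <= 0.5 and np.median(err_r) <= 0.5

    def test_bad_start_frame_rejected(self, two_tool_scene):
        frames = two_tool_scene["frames"]
        scene = two_tool_scene["scene"]
        shape = frames[0].shape
        with pytest.raises(ValueError):
            extract_features(
                frames,
                Roi("left", *roi_for(two_tool_scene["traj_left"][0], scene.tool_radius, shape)),
                Roi("right", *roi_for(two_tool_scene["traj_right"][0], scene.tool_radius, shape)),
                start_frame=len(frames),
            )
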