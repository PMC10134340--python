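import math

import numpy as np
import pytest
from skimage.transform import AffineTransform, warp

from ceustic import phantom as ph
from ceustic import stabilization as st
from ceustic.io import VideoSequence


def make_affine(theta_deg=0.0, tx=0.0, ty=0.0, center=None):
    theta = math.radians(theta_deg)
    lin = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    m = np.eye(3)
    m[:2, :2] = lin
    shift = np.array([tx, ty])
    if center is not None:
        c = np.asarray(center, dtype=float)
        shift = c - lin @ c + shift
    m[:2, 2] = shift
    return AffineTransform(matrix=m)


class TestDetectFeatures:
    def test_uniform_frame_yields_no_features(self):
        assert st.detect_features(np.full((32, 32), 7.0)).shape == (0, 2)

    def test_white_square_corners_localized(self):
        img = np.zeros((32, 32))
        img[10:18, 10:18] = 1.0
        pts = st.detect_features(img, max_n=8, quality=0.2, min_distance=3)
        corners = {(10, 10), (10, 17), (17, 10), (17, 17)}
        assert len(pts) == 4
        for p in pts:
            assert min(max(abs(p[0] - r), abs(p[1] - c)) for r, c in corners) <= 1

    def test_max_n_cap(self, textured_frame):
        pts = st.detect_features(textured_frame, max_n=10, quality=0.001,
                                 min_distance=2)
        assert len(pts) == 10

    def test_min_distance_enforced(self, textured_frame):
        pts = st.detect_features(textured_frame, max_n=50, min_distance=8)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert max(abs(pts[i][0] - pts[j][0]),
                           abs(pts[i][1] - pts[j][1])) >= 8


class TestTrackFeatures:
    def test_identical_frames_zero_displacement(self, textured_frame):
        pts = st.detect_features(textured_frame, max_n=30)
        kept, disp = st.track_features(textured_frame, textured_frame, pts)
        assert len(kept) == len(pts)
        np.testing.assert_allclose(disp, 0.0, atol=1e-3)

    def test_known_shift_recovered(self, textured_frame):
        shifted = np.roll(textured_frame, 5, axis=1)  # +5 columns
        pts = st.detect_features(textured_frame, max_n=50)
        interior = pts[(pts[:, 1] > 10) & (pts[:, 1] < 85)]
        kept, disp = st.track_features(textured_frame, shifted, interior)
        assert len(kept) >= 3
        np.testing.assert_allclose(disp.mean(axis=0), [0.0, 5.0], atol=0.5)

    def test_uncorrelated_noise_mostly_rejected(self, textured_frame):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=textured_frame.shape) * 50 + 100
        pts = st.detect_features(textured_frame, max_n=50)
        kept, _ = st.track_features(textured_frame, noise, pts, fb_threshold=1.0)
        assert len(kept) < 0.5 * len(pts)

    def test_empty_points_rejected(self, textured_frame):
        with pytest.raises(ValueError, match="non-empty"):
            st.track_features(textured_frame, textured_frame, np.empty((0, 2)))


class TestEstimateAffine:
    def test_zero_displacements_give_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (10, 2))
        tform, rms, _ = st.estimate_affine(pts, np.zeros((10, 2)), robust=False)
        np.testing.assert_allclose(tform.params, np.eye(3), atol=1e-10)
        assert rms < 1e-10

    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (20, 2))
        true = make_affine(theta_deg=2.0, tx=3.0, ty=-1.0)
        disp = true(pts[:, ::-1])[:, ::-1] - pts
        tform, _, _ = st.estimate_affine(pts, disp, robust=False)
        np.testing.assert_allclose(tform.params, true.params, atol=1e-6)

    def test_robust_recovery_with_gross_outliers(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, (50, 2))
        true = make_affine(theta_deg=2.0, tx=3.0, ty=-1.0)
        disp = true(pts[:, ::-1])[:, ::-1] - pts
        disp[:10] += rng.uniform(15, 30, (10, 2))  # 20% gross outliers
        tform, _, n_in = st.estimate_affine(pts, disp, robust=True)
        assert n_in >= 35
        np.testing.assert_allclose(tform.params[:2, 2], true.params[:2, 2], atol=0.1)

    def test_too_few_matches(self):
        with pytest.raises(ValueError, match=">= 3"):
            st.estimate_affine(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_collinear_matches(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            st.estimate_affine(pts, np.zeros((5, 2)), robust=False)


class TestSmoothTrajectory:
    @staticmethod
    def translations(xs):
        return [AffineTransform(translation=(x, 0.0)) for x in xs]

    def test_window_one_is_identity(self):
        traj = self.translations([0, 1, 4, 2, 7])
        out = st.smooth_trajectory(traj, window=1)
        for a, b in zip(traj, out):
            np.testing.assert_allclose(a.params, b.params, atol=1e-12)

    def test_linear_trajectory_unchanged_interior(self):
        traj = self.translations(2.0 * np.arange(20))
        out = st.smooth_trajectory(traj, window=5)
        for k in range(2, 18):  # interior frames: moving average of a line
            assert out[k].params[0, 2] == pytest.approx(2.0 * k)

    def test_alternating_jitter_hand_computed(self):
        traj = self.translations([2.0, -2.0, 2.0, -2.0, 2.0])
        out = st.smooth_trajectory(traj, window=3)
        got = [t.params[0, 2] for t in out]
        np.testing.assert_allclose(got, [0.0, 2/3, -2/3, 2/3, 0.0], atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            st.smooth_trajectory(self.translations([0, 1]), window=2)

    def test_rotation_smoothing_preserves_rigidity(self):
        rng = np.random.default_rng(4)
        traj = [make_affine(theta_deg=a) for a in rng.normal(0, 2, 15)]
        out = st.smooth_trajectory(traj, window=5)
        for t in out:  # smoothed transforms stay valid rigid-like affines
            assert np.linalg.det(t.params[:2, :2]) > 0


def _textured_video(n_frames=12, seed=5, shape=(64, 64)):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.normal(size=shape), 1.5) * 50 + 100
    frames = np.stack([base] * n_frames)
    return VideoSequence(frames, np.arange(n_frames) / 5.0)


class TestStabilize:
    def test_still_video_unchanged(self):
        video = _textured_video()
        out, model = st.stabilize(video, window=5)
        np.testing.assert_allclose(out.frames, video.frames, atol=1e-4)
        for t in model.per_frame:
            np.testing.assert_allclose(t.params, np.eye(3), atol=1e-3)

    def test_composition_audit(self):
        video = _textured_video(n_frames=8)
        jit, _ = ph.apply_jitter(video, ph.MotionSpec(sigma_translation=1.5), seed=6)
        _, model = st.stabilize(jit, window=3)
        acc = np.eye(3)
        for k in range(len(model.per_frame)):
            acc = model.per_frame[k].params @ acc if k else np.eye(3)
            np.testing.assert_allclose(model.cumulative[k].params, acc, atol=1e-9)

    def test_jitter_transform_recovery(self):
        video = _textured_video(n_frames=10)
        traj = np.zeros((10, 3))
        traj[:, 0] = np.cumsum([0] + [1.0] * 9)  # steady 1 px/frame row drift
        jit, truth = ph.apply_jitter(video, trajectory=traj)
        _, model = st.stabilize(jit, window=3)
        for k in range(1, 10):
            m_true = truth[k].params @ np.linalg.inv(truth[k - 1].params)
            err = np.abs(model.per_frame[k].params[:2, 2] - m_true[:2, 2]).max()
            assert err < 0.5

    def test_pan_preserved_jitter_removed(self):
        # slow pan + alternating jitter: smoothed trajectory tracks the pan
        video = _textured_video(n_frames=20)
        pan = 0.5 * np.arange(20)
        jitter = np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        traj = np.zeros((20, 3))
        traj[:, 1] = pan + jitter
        jit, _ = ph.apply_jitter(video, trajectory=traj)
        _, model = st.stabilize(jit, window=5)
        smoothed_tx = np.array([t.params[0, 2] for t in model.smoothed])
        fitted = np.polyfit(np.arange(4, 16), smoothed_tx[4:16], 1)
        assert fitted[0] == pytest.approx(0.5, abs=0.15)  # pan slope survives
        residual = smoothed_tx[4:16] - np.polyval(fitted, np.arange(4, 16))
        assert np.abs(residual).max() < 0.5  # jitter removed

    def test_idempotent_on_stabilized_video(self):
        # second pass over an already-stabilized video applies ~no correction
        video = _textured_video(n_frames=40)
        jit, _ = ph.apply_jitter(video, ph.MotionSpec(sigma_translation=0.5), seed=7)
        stab1, _ = st.stabilize(jit, window=15)
        _, model2 = st.stabilize(stab1, window=15)
        resid = [
            np.linalg.norm(
                (model2.cumulative[k].params
                 @ np.linalg.inv(model2.smoothed[k].params))[:2, 2]
            )
            for k in range(len(model2.per_frame))
        ]
        assert np.sqrt(np.mean(np.square(resid))) < 0.5

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            st.stabilize(_textured_video(n_frames=1))

    def test_featureless_video_falls_back_to_identity(self):
        video = VideoSequence(np.zeros((4, 32, 32)), np.arange(4) / 5.0)
        out, model = st.stabilize(video, window=3)  # must not crash
        for t in model.per_frame:
            np.testing.assert_allclose(t.params, np.eye(3))
        np.testing.assert_allclose(out.frames, video.frames, atol=1e-6)
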