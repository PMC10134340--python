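"""Video stabilization by feature tracking and trajectory smoothing.

Breathing and heartbeat displace the probe relative to the pancreas, which
corrupts region tracking and TICs.  The stabilizer follows the classical
feature-point pipeline: Shi–Tomasi corners on each frame, optical-flow
tracking to the next frame with a forward–backward consistency check, a
robust affine fit to the matched displacements, composition into a
cumulative trajectory, moving-average smoothing of the decomposed trajectory
parameters, and compensation warps that retain the smoothed (intentional)
motion while removing the jitter.

All transforms are :class:`skimage.transform.AffineTransform` objects
(x = col, y = row convention); points at the package surface are
``(row, col)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import corner_shi_tomasi
from skimage.measure import ransac
from skimage.registration import optical_flow_ilk
from skimage.transform import AffineTransform, warp

from .io import VideoSequence

log = logging.getLogger(__name__)

IDENTITY = AffineTransform()


# ---------------------------------------------------------------------------
# feature detection and tracking
# ---------------------------------------------------------------------------

def detect_features(
    frame: np.ndarray,
    max_n: int = 200,
    quality: float = 0.01,
    min_distance: int = 8,
) -> np.ndarray:
    """Shi–Tomasi corners, strongest first.

    Returns an ``(n, 2)`` array of ``(row, col)`` points with ``n <= max_n``;
    every point's minimum-eigenvalue response is at least ``quality`` times
    the image maximum, accepted points are pairwise at least ``min_distance``
    px apart (greedy suppression in response order), and ties in response
    break by ascending ``(row, col)``.  A constant frame yields zero features.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        log.warning("constant frame: no corners detected")
        return np.empty((0, 2), dtype=int)
    response = corner_shi_tomasi(frame)
    r_max = response.max()
    if r_max <= 0:
        log.warning("constant or featureless frame: no corners detected")
        return np.empty((0, 2), dtype=int)
    rows, cols = np.nonzero(response >= quality * r_max)
    resp = response[rows, cols]
    order = np.lexsort((cols, rows, -resp))  # response desc, then (row, col) asc
    selected: list[tuple[int, int]] = []
    for i in order:
        p = (rows[i], cols[i])
        if all(
            max(abs(p[0] - q[0]), abs(p[1] - q[1])) >= min_distance for q in selected
        ):
            selected.append(p)
            if len(selected) == max_n:
                break
    return np.asarray(selected, dtype=int).reshape(-1, 2)


def _sample_flow(flow: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear sample of a (2, H, W) flow field at float (row, col) points."""
    h, w = flow.shape[1:]
    r = np.clip(points[:, 0], 0, h - 1)
    c = np.clip(points[:, 1], 0, w - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2) if h > 1 else np.zeros_like(r, int)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2) if w > 1 else np.zeros_like(c, int)
    fr, fc = r - r0, c - c0
    out = np.empty((points.shape[0], 2))
    for axis in range(2):
        f = flow[axis]
        out[:, axis] = (
            f[r0, c0] * (1 - fr) * (1 - fc)
            + f[r0 + 1, c0] * fr * (1 - fc)
            + f[r0, c0 + 1] * (1 - fr) * fc
            + f[r0 + 1, c0 + 1] * fr * fc
        )
    return out


def track_features(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points: np.ndarray,
    fb_threshold: float = 1.0,
    radius: int = 7,
    prealign: bool = True,
):
    """Track points from ``prev_frame`` to ``next_frame`` by iterative
    Lucas–Kanade optical flow with a forward–backward consistency check.

    With ``prealign`` a coarse global translation from phase correlation is
    removed first (coarse-to-fine), so displacements beyond the local flow
    window remain trackable.  Returns ``(retained_points, displacements)``:
    ``(row, col)`` points kept and their ``(drow, dcol)`` displacement.  A
    point is dropped when the backward-tracked position misses its start by
    more than ``fb_threshold`` px.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] == 0:
        raise ValueError("points must be non-empty")
    prev = np.asarray(prev_frame, dtype=float)
    nxt = np.asarray(next_frame, dtype=float)

    coarse = np.zeros(2)
    if prealign:
        from scipy.ndimage import shift as _ndshift
        from skimage.registration import phase_cross_correlation

        shift, _, _ = phase_cross_correlation(prev, nxt, upsample_factor=4)
        coarse = -np.asarray(shift)  # content displacement prev -> next
        if np.abs(coarse).max() > 0.25:
            # undo the coarse motion so only the residual remains for the flow
            nxt = _ndshift(nxt, -coarse, order=1, mode="nearest")
        else:
            coarse = np.zeros(2)

    fwd = optical_flow_ilk(prev, nxt, radius=radius)  # next(p + d) ~ prev(p)
    bwd = optical_flow_ilk(nxt, prev, radius=radius)
    disp = _sample_flow(fwd, points)
    back = _sample_flow(bwd, points + disp)
    fb_err = np.linalg.norm(disp + back, axis=1)
    keep = fb_err <= fb_threshold
    return points[keep], disp[keep] + coarse


# ---------------------------------------------------------------------------
# affine estimation and trajectory smoothing
# ---------------------------------------------------------------------------

def estimate_affine(
    points: np.ndarray,
    displacements: np.ndarray,
    robust: bool = True,
    residual_threshold: float = 1.0,
):
    """Least-squares (or RANSAC-consensus) affine from matched displacements.

    ``points`` are ``(row, col)`` positions in the previous frame and
    ``displacements`` their ``(drow, dcol)`` motion into the next frame.
    Returns ``(transform, rms_residual, n_inliers)``; the transform maps
    previous-frame coordinates to next-frame coordinates (x, y convention).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    displacements = np.asarray(displacements, dtype=float).reshape(-1, 2)
    if points.shape[0] < 3:
        raise ValueError(
            f"affine estimation needs >= 3 matches, got {points.shape[0]}"
        )
    src = points[:, ::-1]  # (row, col) -> (x, y)
    dst = (points + displacements)[:, ::-1]
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("matches are collinear; affine is underdetermined")

    if robust and points.shape[0] >= 4:
        model, inliers = ransac(
            (src, dst),
            AffineTransform,
            min_samples=3,
            residual_threshold=residual_threshold,
            max_trials=200,
            rng=0,
        )
        if model is not None and inliers is not None and inliers.sum() >= 3:
            refit = AffineTransform.from_estimate(src[inliers], dst[inliers])
            if refit:
                res = np.linalg.norm(refit(src[inliers]) - dst[inliers], axis=1)
                return refit, float(np.sqrt((res**2).mean())), int(inliers.sum())
        # degenerate consensus: fall through to plain least squares
    tform = AffineTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("affine estimation failed (degenerate geometry)")
    res = np.linalg.norm(tform(src) - dst, axis=1)
    return tform, float(np.sqrt((res**2).mean())), points.shape[0]


_PARAM_COLS = ["tx", "ty", "rotation", "scale_x", "scale_y", "shear"]


def decompose_affine(tform: AffineTransform) -> np.ndarray:
    """Decompose into (tx, ty, rotation, scale_x, scale_y, shear)."""
    sx, sy = tform.scale if np.ndim(tform.scale) else (tform.scale, tform.scale)
    return np.array(
        [tform.translation[0], tform.translation[1], tform.rotation, sx, sy, tform.shear]
    )


def compose_affine(params: np.ndarray) -> AffineTransform:
    tx, ty, rot, sx, sy, shear = params
    return AffineTransform(
        scale=(sx, sy), rotation=rot, shear=shear, translation=(tx, ty)
    )


def smooth_trajectory(
    transforms: list[AffineTransform], window: int = 15
) -> list[AffineTransform]:
    """Moving-average smoothing of the decomposed cumulative trajectory.

    Each parameter (translation x/y, rotation, scales, shear) is replaced by
    its centered moving average over ``window`` frames; the window shrinks at
    the sequence edges.  ``window`` must be odd; ``window=1`` is the
    identity.  Smoothing the raw matrix entries instead can produce
    degenerate transforms, hence the decomposition.
    """
    from .tic import moving_average

    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    params = np.stack([decompose_affine(t) for t in transforms])
    params[:, 2] = np.unwrap(params[:, 2])
    smoothed = np.column_stack(
        [moving_average(params[:, j], window) for j in range(params.shape[1])]
    )
    return [compose_affine(p) for p in smoothed]


@dataclass
class MotionModel:
    """Audit record of the stabilization: per-frame, cumulative and smoothed
    affine transforms (frame 0 is the identity for all three)."""

    per_frame: list[AffineTransform]
    cumulative: list[AffineTransform]
    smoothed: list[AffineTransform]

    def __post_init__(self) -> None:
        n = len(self.per_frame)
        if not (len(self.cumulative) == len(self.smoothed) == n):
            raise ValueError("trajectory lists must have equal length")
        for t in self.per_frame:
            if not np.all(np.isfinite(t.params)):
                raise ValueError("affine entries must be finite")
            if np.linalg.det(t.params[:2, :2]) <= 0:
                raise ValueError("affine linear part must have positive determinant")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.per_frame):
            a = t.params
            rows.append(
                {
                    "frame": k,
                    "a11": a[0, 0], "a12": a[0, 1], "a13": a[0, 2],
                    "a21": a[1, 0], "a22": a[1, 1], "a23": a[1, 2],
                }
            )
        return pd.DataFrame(rows)


def _normalize_to_first(transforms: list[AffineTransform]) -> list[AffineTransform]:
    """Re-anchor a trajectory so its first element is the identity."""
    inv0 = AffineTransform(matrix=np.linalg.inv(transforms[0].params))
    return [AffineTransform(matrix=t.params @ inv0.params) for t in transforms]


def stabilize(
    video: VideoSequence,
    max_features: int = 200,
    quality: float = 0.01,
    min_distance: int = 8,
    fb_threshold: float = 1.0,
    window: int = 15,
    robust: bool = True,
):
    """Stabilize a video; returns ``(stabilized VideoSequence, MotionModel)``.

    Frame ``k`` is warped by ``smoothed_k ∘ cumulative_k⁻¹`` (bilinear,
    edge-replicated borders); the first frame is unchanged.  A frame whose
    tracking or affine fit fails falls back to the identity transform with a
    logged warning — stabilization never aborts mid-video.  The result is
    deterministic given the video.
    """
    if video.n_frames < 2:
        raise ValueError("stabilization needs at least 2 frames")
    frames = video.frames.astype(float)

    def translation_fallback(k: int) -> AffineTransform:
        # corners untrackable (e.g. frame dominated by border replication):
        # keep at least the dominant rigid translation from phase correlation
        from skimage.registration import phase_cross_correlation

        if np.ptp(frames[k - 1]) == 0 or np.ptp(frames[k]) == 0:
            return IDENTITY  # constant frames carry no registration signal
        shift, _, _ = phase_cross_correlation(
            frames[k - 1], frames[k], upsample_factor=4
        )
        if not np.all(np.isfinite(shift)):
            return IDENTITY
        return AffineTransform(translation=(-shift[1], -shift[0]))

    per_frame: list[AffineTransform] = [IDENTITY]
    for k in range(1, video.n_frames):
        tform = None
        try:
            pts = detect_features(frames[k - 1], max_features, quality, min_distance)
            if pts.shape[0] >= 3:
                kept, disp = track_features(
                    frames[k - 1], frames[k], pts, fb_threshold
                )
                if kept.shape[0] >= 3:
                    tform, _, _ = estimate_affine(kept, disp, robust=robust)
                else:
                    log.warning("frame %d: <3 tracked points; translation fallback", k)
            else:
                log.warning("frame %d: <3 corners; translation fallback", k)
        except ValueError as exc:
            log.warning("frame %d: %s; translation fallback", k, exc)
        if tform is None:
            tform = translation_fallback(k)
        per_frame.append(tform)

    cumulative = [IDENTITY]
    for t in per_frame[1:]:
        cumulative.append(AffineTransform(matrix=t.params @ cumulative[-1].params))
    smoothed = _normalize_to_first(smooth_trajectory(cumulative, window))

    out = np.empty_like(frames, dtype=np.float32)
    out[0] = frames[0]
    for k in range(1, video.n_frames):
        # output(q) = frame_k(C_k(S_k⁻¹(q))): map output coords back through
        # the smoothed trajectory, forward through the measured one.
        inv_map = AffineTransform(
            matrix=cumulative[k].params @ np.linalg.inv(smoothed[k].params)
        )
        out[k] = warp(frames[k], inv_map, order=1, mode="edge", preserve_range=True)

    model = MotionModel(per_frame, cumulative, smoothed)
    stab = VideoSequence(
        out, video.timestamps.copy(), t_inject=video.t_inject, frame_rate=video.frame_rate
    )
    return stab, model


def frame_displacement_rms(video: VideoSequence, upsample: int = 10) -> float:
    """RMS frame-to-frame rigid displacement, measured by phase correlation.

    Independent of the tracking pipeline; used to audit stabilization
    quality.
    """
    from skimage.registration import phase_cross_correlation

    shifts = []
    for k in range(1, video.n_frames):
        shift, _, _ = phase_cross_correlation(
            video.frames[k - 1].astype(float),
            video.frames[k].astype(float),
            upsample_factor=upsample,
        )
        shifts.append(shift)
    shifts = np.asarray(shifts)
    return float(np.sqrt((shifts**2).sum(axis=1).mean()))
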