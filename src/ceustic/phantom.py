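"""Synthetic contrast-enhancement phantoms.

Generates CH-EUS-like grayscale videos with known ground truth so every
downstream stage (stabilization, segmentation, TIC extraction,
classification, thermogram) is testable without clinical data.

Model
-----
Each tissue class follows a gamma-variate bolus curve, the standard
first-pass contrast-kinetics form::

    I(t) = b + A * u**alpha * exp(alpha * (1 - u)),   u = (t - t0) / tp

for ``t > t0`` and ``I(t) = b`` otherwise.  The curve leaves baseline ``b``
at arrival time ``t0``, attains its maximum ``b + A`` exactly at
``t0 + tp`` and relaxes back to ``b``.  Defaults emulate the qualitative
clinical picture: pancreatic adenocarcinoma is hypoenhanced in all phases
with delayed wash-in (here amplitude ratio 0.5 and time-to-peak ratio 1.5
versus parenchyma), mass-forming pancreatitis is iso- to hyperenhanced, and
necrosis does not enhance at all (A = 0).

Speckle is multiplicative, gamma-distributed with mean 1 and dispersion
``sigma_speckle``, drawn once per video as a static field (ultrasound
speckle is tissue-locked).  Breathing/heartbeat motion is applied separately
by :func:`apply_jitter` as a per-frame affine warp with the ground-truth
trajectory returned for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import AffineTransform, warp

from .io import ROIMask, VideoSequence

INTENSITY_MAX = 255.0


@dataclass(frozen=True)
class PerfusionClass:
    """Gamma-variate bolus parameters for one tissue class.

    amplitude : peak enhancement above baseline (a.u.)
    t0        : contrast arrival time after injection (s)
    tp        : time from arrival to peak (s); the peak sits at ``t0 + tp``
    alpha     : dimensionless shape; smaller alpha -> broader curve
    baseline  : pre-contrast echo intensity (a.u.)
    """

    name: str
    amplitude: float
    t0: float
    tp: float
    alpha: float
    baseline: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tp <= 0 or self.alpha <= 0:
            raise ValueError("tp and alpha must be > 0")


# Study-condition defaults: 90 s observation at 5 frames/s, injection at t=0,
# parenchymal arrival at 10 s (start of the arterial phase), peak at 25 s.
PARENCHYMA = PerfusionClass("parenchyma", amplitude=100.0, t0=10.0, tp=15.0, alpha=1.5, baseline=5.0)
CANCEROUS = PerfusionClass("cancerous", amplitude=50.0, t0=10.0, tp=22.5, alpha=1.5, baseline=5.0)
INFLAMMATORY = PerfusionClass("inflammatory", amplitude=115.0, t0=10.0, tp=15.0, alpha=1.5, baseline=5.0)
NECROTIC = PerfusionClass("necrotic", amplitude=0.0, t0=10.0, tp=15.0, alpha=1.5, baseline=5.0)

DEFAULT_CLASSES = {c.name: c for c in (PARENCHYMA, CANCEROUS, INFLAMMATORY, NECROTIC)}


def bolus_intensity(t, cls: PerfusionClass):
    """Evaluate the gamma-variate bolus curve at time(s) ``t`` (s post-injection).

    Scalar in, scalar out; array in, array out.  Negative times are an error
    (the clock starts at injection).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (seconds after injection)")
    u = (t_arr - cls.t0) / cls.tp
    out = np.full(t_arr.shape, cls.baseline, dtype=float)
    rising = u > 0
    uu = u[rising]
    out[rising] = cls.baseline + cls.amplitude * uu**cls.alpha * np.exp(
        cls.alpha * (1.0 - uu)
    )
    return out if np.ndim(t) else float(out)


@dataclass
class MotionSpec:
    """Random-walk rigid jitter: per-frame N(0, sigma) increments."""

    sigma_translation: float = 0.0  # px/frame, each axis
    sigma_rotation: float = 0.0  # radians/frame

    def __post_init__(self) -> None:
        if self.sigma_translation < 0 or self.sigma_rotation < 0:
            raise ValueError("motion sigmas must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry, kinetics, noise and timing of one synthetic examination."""

    shape: tuple[int, int] = (128, 128)
    mass_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    mass_axes: tuple[float, float] = (28.0, 20.0)  # semi-axes (row, col)
    mass_class: str = "cancerous"
    core_axes: tuple[float, float] | None = None  # necrotic core semi-axes
    parenchyma_box: tuple[int, int, int, int] = (8, 32, 8, 32)  # ROI 2: r0,r1,c0,c1
    classes: dict[str, PerfusionClass] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    sigma_speckle: float = 0.1
    motion: MotionSpec = field(default_factory=MotionSpec)
    duration: float = 90.0  # s; covers the venous-phase end
    fps: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_speckle < 0:
            raise ValueError("sigma_speckle must be >= 0")
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be > 0")
        h, w = self.shape
        r, c = self.mass_center
        ar, ac = self.mass_axes
        if not (ar < r < h - ar and ac < c < w - ac):
            raise ValueError("mass ellipse must lie inside the image")
        if self.core_axes is not None and (
            self.core_axes[0] >= ar or self.core_axes[1] >= ac
        ):
            raise ValueError("necrotic core must lie inside the mass")
        if self.mass_class not in self.classes:
            raise ValueError(f"unknown mass_class {self.mass_class!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps)) + 1

    @property
    def label(self) -> str:
        return "malignant" if self.mass_class == "cancerous" else "benign"


def _region_maps(spec: PhantomSpec):
    """Boolean masks for mass (ROI 1, core included), parenchyma box and core."""
    h, w = spec.shape
    mass = np.zeros(spec.shape, dtype=bool)
    rr, cc = _draw_ellipse(*spec.mass_center, *spec.mass_axes, shape=spec.shape)
    mass[rr, cc] = True
    core = np.zeros(spec.shape, dtype=bool)
    if spec.core_axes is not None:
        rr, cc = _draw_ellipse(*spec.mass_center, *spec.core_axes, shape=spec.shape)
        core[rr, cc] = True
    r0, r1, c0, c1 = spec.parenchyma_box
    paren = np.zeros(spec.shape, dtype=bool)
    paren[r0:r1, c0:c1] = True
    paren &= ~mass  # ROI 1 and ROI 2 are disjoint by construction
    return mass, paren, core


def _speckle_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.ones(shape)
    k = 1.0 / sigma**2  # gamma with mean 1, sd sigma
    return rng.gamma(shape=k, scale=1.0 / k, size=shape)


def render_phantom(spec: PhantomSpec, seed: int | None = None):
    """Render a phantom examination.

    Returns ``(video, masks, label, truth_tics)`` where ``masks`` maps
    ``{"mass", "parenchyma", "core"}`` to ground-truth :class:`ROIMask`,
    ``label`` is ``"benign"``/``"malignant"`` and ``truth_tics`` maps region
    name to the noiseless bolus curve sampled at the frame times.  Pixel
    values are class bolus intensity times the static speckle field, clipped
    to ``[0, 255]``.  The same seed yields bit-identical output.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(spec.n_frames) / spec.fps
    mass, paren_box, core = _region_maps(spec)

    class_names = ["parenchyma", spec.mass_class, "necrotic"]
    class_idx = np.zeros(spec.shape, dtype=np.int8)
    class_idx[mass] = 1
    class_idx[core] = 2
    curves = np.stack(
        [bolus_intensity(times, spec.classes[n]) for n in class_names]
    )  # (3, T)

    speckle = _speckle_field(spec.shape, spec.sigma_speckle, rng).astype(np.float32)
    frames = curves[class_idx].transpose(2, 0, 1).astype(np.float32)  # (T, H, W)
    frames *= speckle[None]
    np.clip(frames, 0.0, INTENSITY_MAX, out=frames)

    video = VideoSequence(frames, times, t_inject=0.0, frame_rate=spec.fps)
    masks = {
        "mass": ROIMask(mass, role="mass", source="phantom-truth"),
        "parenchyma": ROIMask(paren_box, role="parenchyma", source="phantom-truth"),
        "core": ROIMask(core, role="necrotic-core", source="phantom-truth"),
    }
    truth_tics = {
        "mass": (times, curves[1].copy()),
        "parenchyma": (times, curves[0].copy()),
        "core": (times, curves[2].copy()),
    }
    return video, masks, spec.label, truth_tics


def _rigid_about_center(dy: float, dx: float, theta: float, shape) -> AffineTransform:
    """Rigid transform (x, y convention): rotation ``theta`` about the image
    center followed by translation ``(dx, dy)`` in pixels."""
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    cos, sin = math.cos(theta), math.sin(theta)
    lin = np.array([[cos, -sin], [sin, cos]])
    shift = np.array([cx, cy]) - lin @ np.array([cx, cy]) + np.array([dx, dy])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = shift
    return AffineTransform(matrix=m)


def jitter_trajectory(
    n_frames: int, motion: MotionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk cumulative trajectory, shape (T, 3): (dy, dx, theta); row 0 zero."""
    steps = np.zeros((n_frames, 3))
    steps[1:, 0] = rng.normal(0, motion.sigma_translation, n_frames - 1)
    steps[1:, 1] = rng.normal(0, motion.sigma_translation, n_frames - 1)
    steps[1:, 2] = rng.normal(0, motion.sigma_rotation, n_frames - 1)
    return np.cumsum(steps, axis=0)


def apply_jitter(
    video: VideoSequence,
    motion: MotionSpec | None = None,
    seed: int | None = None,
    trajectory: np.ndarray | None = None,
):
    """Warp each frame by a cumulative rigid trajectory.

    Either pass an explicit ``trajectory`` — shape (T, 3) rows of cumulative
    ``(dy, dx, theta)`` — or a :class:`MotionSpec` whose random walk is drawn
    with ``seed``.  Frame ``k`` of the output is frame ``k`` of the input
    warped by the cumulative transform; borders are edge-replicated.

    Returns ``(jittered_video, truth_transforms)`` where ``truth_transforms``
    is the list of cumulative :class:`AffineTransform` (point motion, frame-0
    frame of reference; entry 0 is the identity).
    """
    if trajectory is None:
        if motion is None:
            raise ValueError("provide either a MotionSpec or an explicit trajectory")
        trajectory = jitter_trajectory(
            video.n_frames, motion, np.random.default_rng(seed)
        )
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != (video.n_frames, 3):
        raise ValueError("trajectory must have shape (n_frames, 3)")

    shape = video.frame_shape
    transforms = [
        _rigid_about_center(dy, dx, th, shape) for dy, dx, th in trajectory
    ]
    out = np.empty_like(video.frames, dtype=np.float32)
    out[0] = video.frames[0]
    for k in range(1, video.n_frames):
        out[k] = warp(
            video.frames[k].astype(float),
            transforms[k].inverse,
            order=1,
            mode="edge",
            preserve_range=True,
        )
    jittered = VideoSequence(
        out, video.timestamps.copy(), t_inject=video.t_inject, frame_rate=video.frame_rate
    )
    return jittered, transforms


def gamma_variate_auc(cls: PerfusionClass, t_end: float) -> float:
    """Closed-form integral of the baseline-corrected bolus on [0, t_end].

    With u = (t - t0)/tp the enhancement integrates to
    ``A tp e^alpha gamma(alpha+1, alpha u_end) / alpha^(alpha+1)`` where
    gamma is the lower incomplete gamma function.
    """
    from scipy.special import gamma as _gamma, gammainc

    if t_end <= cls.t0:
        return 0.0
    u_end = (t_end - cls.t0) / cls.tp
    a = cls.alpha
    lower_inc = gammainc(a + 1, a * u_end) * _gamma(a + 1)  # unregularized
    return float(cls.amplitude * cls.tp * math.exp(a) * lower_inc / a ** (a + 1))


# ---------------------------------------------------------------------------
# feature-table and cohort generators
# ---------------------------------------------------------------------------

FEATURE_NAMES = ["ttp_s", "pi", "auc", "pd", "rpd"]


def _class_feature_vector(cls: PerfusionClass, parenchyma: PerfusionClass,
                          duration: float, fps: float) -> np.ndarray:
    """Noiseless five-parameter TIC vector of a class against parenchyma."""
    from . import tic as _tic  # local import; tic does not import phantom

    times = np.arange(int(round(duration * fps)) + 1) / fps
    mass_curve = _tic.TICCurve(times, bolus_intensity(times, cls), region_id=cls.name)
    paren_curve = _tic.TICCurve(
        times, bolus_intensity(times, parenchyma), region_id="parenchyma"
    )
    feats = _tic.tic_features(
        _tic.preprocess_tic(mass_curve, baseline_window=(0.0, parenchyma.t0 / 2)),
        _tic.preprocess_tic(paren_curve, baseline_window=(0.0, parenchyma.t0 / 2)),
        t_end=duration,
    )
    return feats.to_array()


def make_feature_dataset(
    n_benign: int,
    n_malignant: int,
    benign_class: PerfusionClass = INFLAMMATORY,
    malignant_class: PerfusionClass = CANCEROUS,
    parenchyma: PerfusionClass = PARENCHYMA,
    noise_sigma: float = 0.1,
    duration: float = 90.0,
    fps: float = 5.0,
    seed: int | None = None,
):
    """Draw a synthetic five-parameter feature table with labels.

    Each row is the class's noiseless (TTP, PI, AUC, PD, RPD) vector plus
    additive Gaussian noise of standard deviation ``noise_sigma`` times the
    per-feature characteristic scale (the larger of the two class magnitudes).
    Returns ``(DataFrame[ttp_s, pi, auc, pd, rpd], labels array)``.
    """
    import pandas as pd

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("both classes must be represented (n >= 1 each)")
    rng = np.random.default_rng(seed)
    mu_b = _class_feature_vector(benign_class, parenchyma, duration, fps)
    mu_m = _class_feature_vector(malignant_class, parenchyma, duration, fps)
    scale = np.maximum(np.maximum(np.abs(mu_b), np.abs(mu_m)), 1e-6)
    rows = np.concatenate(
        [
            mu_b + rng.normal(0, noise_sigma, (n_benign, 5)) * scale,
            mu_m + rng.normal(0, noise_sigma, (n_malignant, 5)) * scale,
        ]
    )
    labels = np.array(["benign"] * n_benign + ["malignant"] * n_malignant)
    return pd.DataFrame(rows, columns=FEATURE_NAMES), labels


def sample_phantom_cohort(
    n_benign: int,
    n_malignant: int,
    base_spec: PhantomSpec | None = None,
    seed: int | None = None,
    geometry_jitter: float = 6.0,
    kinetic_jitter: float = 0.10,
):
    """Draw a cohort of randomized phantom specs with labels.

    Geometry (mass center and semi-axes) and the mass class's amplitude and
    time-to-peak vary mildly between masses (lognormal multipliers with
    dispersion ``kinetic_jitter``) so the classification task is non-trivial.
    Returns a list of ``(PhantomSpec, label)``.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for lab in labels:
        cls_name = "cancerous" if lab == "malignant" else "inflammatory"
        cls = base.classes[cls_name]
        cls = replace(
            cls,
            amplitude=cls.amplitude * rng.lognormal(0, kinetic_jitter),
            tp=cls.tp * rng.lognormal(0, kinetic_jitter / 2),
        )
        h, w = base.shape
        ar = base.mass_axes[0] * rng.uniform(0.85, 1.15)
        ac = base.mass_axes[1] * rng.uniform(0.85, 1.15)
        r = np.clip(
            base.mass_center[0] + rng.uniform(-geometry_jitter, geometry_jitter),
            ar + 1, h - ar - 1,
        )
        c = np.clip(
            base.mass_center[1] + rng.uniform(-geometry_jitter, geometry_jitter),
            ac + 1, w - ac - 1,
        )
        classes = dict(base.classes)
        classes[cls_name] = cls
        spec = replace(
            base,
            mass_center=(float(r), float(c)),
            mass_axes=(float(ar), float(ac)),
            mass_class=cls_name,
            classes=classes,
        )
        cohort.append((spec, lab))
    return cohort
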