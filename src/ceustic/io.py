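"""Frame-stack, mask, annotation and report I/O.

Contrast-enhanced EUS recordings arrive as grayscale frame stacks
(multi-page TIFF or a directory of numbered PNGs) with a sidecar YAML file
carrying the acquisition clock: either explicit per-frame ``timestamps`` or a
``frame_rate``, plus the contrast-injection time ``t_inject`` on the same
clock.  Intensities are kept in their native integer (or float) units and
only converted to floating point inside TIC extraction.

Coordinates are 0-based, row-major ``(row, col)`` throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as _draw_polygon

DEFAULT_FRAME_RATE = 5.0  # frames/s; live EUS feeds run at five frames per second


class MetadataError(ValueError):
    """A required sidecar metadata field is missing or inconsistent."""


@dataclass
class VideoSequence:
    """A time-stamped grayscale frame stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Grayscale frames, intensity in arbitrary units (a.u.).
    timestamps : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.
    t_inject : float
        Contrast-injection time (s) on the same clock as ``timestamps``.
    frame_rate : float
        Nominal frame rate (frames/s); metadata only.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    t_inject: float = 0.0
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("timestamps length must equal the number of frames")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.t_inject < 0:
            raise ValueError("t_inject must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_post_injection(self) -> np.ndarray:
        """Frame times in seconds relative to contrast injection."""
        return self.timestamps - self.t_inject


@dataclass
class DualPanelFrame:
    """A side-by-side console frame: EUS panel (left) | CH-EUS panel (right)."""

    full: np.ndarray
    left: np.ndarray
    right: np.ndarray
    split_column: int


@dataclass
class ROIMask:
    """Binary region mask with its clinical role.

    ``role`` is ``"mass"`` (ROI 1), ``"parenchyma"`` (ROI 2) or another
    free-form tag; ``source`` records provenance (manual, segmenter,
    phantom-truth).
    """

    mask: np.ndarray
    role: str = "mass"
    source: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D image")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


# ---------------------------------------------------------------------------
# video I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "meta.yaml"
    return path.with_suffix(".yaml")


def _load_sidecar(path: Path, n_frames: int) -> tuple[np.ndarray, float, float]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"sidecar metadata file not found: {sidecar} "
            "(expected fields: timestamps or frame_rate, t_inject)"
        )
    meta = yaml.safe_load(sidecar.read_text()) or {}
    if "t_inject" not in meta:
        raise MetadataError(f"sidecar {sidecar} is missing required field 't_inject'")
    t_inject = float(meta["t_inject"])
    if "timestamps" in meta:
        timestamps = np.asarray(meta["timestamps"], dtype=float)
        if timestamps.size != n_frames:
            raise MetadataError(
                f"sidecar {sidecar}: {timestamps.size} timestamps for {n_frames} frames"
            )
        frame_rate = float(meta.get("frame_rate", _infer_rate(timestamps)))
    elif "frame_rate" in meta:
        frame_rate = float(meta["frame_rate"])
        timestamps = np.arange(n_frames, dtype=float) / frame_rate
    else:
        raise MetadataError(
            f"sidecar {sidecar} must provide either 'timestamps' or 'frame_rate'"
        )
    return timestamps, t_inject, frame_rate


def _infer_rate(timestamps: np.ndarray) -> float:
    if timestamps.size < 2:
        return DEFAULT_FRAME_RATE
    return 1.0 / float(np.median(np.diff(timestamps)))


def read_video(path: str | Path, layout: str | None = None) -> VideoSequence:
    """Read a frame stack plus its sidecar metadata.

    ``layout`` is ``"tiff-stack"``, ``"png-dir"`` or None (inferred from the
    path).  Intensities are preserved without rescaling; frames are ordered
    by timestamp (file order for a TIFF stack, lexicographic file order for a
    PNG directory).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout is None:
        layout = "png-dir" if path.is_dir() else "tiff-stack"

    if layout == "tiff-stack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    elif layout == "png-dir":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise ValueError(f"no PNG frames found in directory {path}")
        images = [iio.imread(f) for f in files]
        shapes = {im.shape for im in images}
        if len(shapes) > 1:
            bad = next(
                i for i, im in enumerate(images) if im.shape != images[0].shape
            )
            raise ValueError(
                f"inconsistent frame shapes: frame {bad} ({files[bad].name}) has "
                f"shape {images[bad].shape}, expected {images[0].shape}"
            )
        frames = np.stack(images)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    timestamps, t_inject, frame_rate = _load_sidecar(path, frames.shape[0])
    return VideoSequence(frames, timestamps, t_inject=t_inject, frame_rate=frame_rate)


def write_video(video: VideoSequence, path: str | Path) -> Path:
    """Write a multi-page TIFF stack plus its YAML sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, video.frames)
    meta = {
        "timestamps": [float(t) for t in video.timestamps],
        "t_inject": float(video.t_inject),
        "frame_rate": float(video.frame_rate),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))
    return path


def split_dual_panel(frame: np.ndarray, split_column: int | str = "auto") -> DualPanelFrame:
    """Split a side-by-side console frame into EUS (left) and CH-EUS (right) panels.

    With ``split_column="auto"`` the mark line is taken at ``floor(W/2)``;
    for an odd width the right (CH-EUS) panel gets the extra column.
    """
    frame = np.asarray(frame)
    if frame.ndim < 2 or frame.shape[1] < 2:
        raise ValueError("frame must be 2-D with width >= 2")
    col = frame.shape[1] // 2 if split_column == "auto" else int(split_column)
    if not 0 < col < frame.shape[1]:
        raise ValueError(f"split_column {col} outside frame width {frame.shape[1]}")
    return DualPanelFrame(
        full=frame, left=frame[:, :col], right=frame[:, col:], split_column=col
    )


# ---------------------------------------------------------------------------
# masks and annotations
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, role: str = "mass", source: str = "manual") -> ROIMask:
    """Read a binary PNG mask; non-binary images are binarized at > 0 with a warning."""
    img = iio.imread(Path(path))
    if img.ndim == 3:  # RGB(A) mask: any nonzero channel marks the region
        img = img[..., :3].max(axis=-1)
    values = np.unique(img)
    if values.size > 2:
        warnings.warn(
            f"mask {path} is not binary ({values.size} distinct values); "
            "binarizing at > 0",
            stacklevel=2,
        )
    mask = ROIMask(img > 0, role=role, source=source)
    if mask.is_empty:
        warnings.warn(f"mask {path} is empty", stacklevel=2)
    return mask


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


def polygon_to_mask(
    points: np.ndarray, shape: tuple[int, int], role: str = "mass"
) -> ROIMask:
    """Rasterize an ``(n, 2)`` array of ``(row, col)`` polygon vertices."""
    points = np.asarray(points, dtype=float)
    rr, cc = _draw_polygon(points[:, 0], points[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return ROIMask(mask, role=role, source="manual")


def read_polygon_annotation(path: str | Path, shape: tuple[int, int]) -> ROIMask:
    """Read a VIA-style polygon annotation JSON and rasterize the first region.

    Accepts either ``{"regions": [{"shape_attributes": {"all_points_x": [...],
    "all_points_y": [...]}}]}`` (VIA point lists, x = col, y = row) or the
    package's own ``{"points": [[row, col], ...]}``.
    """
    data = json.loads(Path(path).read_text())
    if "regions" in data:
        sa = data["regions"][0]["shape_attributes"]
        pts = np.column_stack([sa["all_points_y"], sa["all_points_x"]])
    elif "points" in data:
        pts = np.asarray(data["points"], dtype=float)
    else:
        raise ValueError(f"unrecognized annotation format in {path}")
    return polygon_to_mask(pts, shape)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(results, path: str | Path, format: str | None = None) -> Path:
    """Serialize results (dict / dataclass / list of records) to JSON or CSV.

    Numeric fields round-trip at full precision: JSON uses ``repr`` floats and
    CSV is written through pandas without rounding.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    plain = _to_plain(results)
    if format == "json":
        path.write_text(json.dumps(plain, indent=2))
    elif format == "csv":
        records = plain if isinstance(plain, list) else [plain]
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path):
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, float_precision="round_trip")
    return json.loads(path.read_text())
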