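"""Time–intensity curves and their five-parameter summary.

The mass region (ROI 1) is tiled into square subregions (ROI 1 N); each
subregion's mean-intensity trace over time is a TIC.  After baseline
subtraction and optional smoothing, five parameters summarize each mass TIC
against the parenchymal reference TIC (ROI 2):

TTP  time to peak (s, from injection)
PI   peak intensity (a.u., baseline-corrected)
AUC  trapezoidal area under the curve on [0, T_end] (a.u.·s)
PD   peak difference, PI_mass − PI_parenchyma (negative for hypoenhanced masses)
RPD  relative peak difference, PD / PI_parenchyma (dimensionless)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ROIMask, VideoSequence

FEATURE_NAMES = ["ttp_s", "pi", "auc", "pd", "rpd"]


@dataclass
class GridCell:
    """One s×s tile of the subregion grid, clipped to the image.

    ``rows``/``cols`` index the pixels of the tile that fall inside ROI 1;
    the TIC of the cell is taken over exactly those pixels.
    """

    cell_id: int
    row0: int
    row1: int
    col0: int
    col1: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row0 + self.row1 - 1) / 2.0, (self.col0 + self.col1 - 1) / 2.0)

    @property
    def grid_index(self) -> tuple[int, int]:
        """(tile-row, tile-col) index within the grid tiling."""
        return self._grid_index

    _grid_index: tuple[int, int] = (0, 0)


@dataclass
class SubregionGrid:
    """Axis-aligned s×s tiling of ROI 1, anchored at its bounding-box corner."""

    cell_side: int
    min_coverage: float
    cells: list[GridCell]
    mask: ROIMask

    def __len__(self) -> int:
        return len(self.cells)


def subdivide_roi(
    mask: ROIMask | np.ndarray, cell_side: int = 32, min_coverage: float = 0.5
) -> SubregionGrid:
    """Tile ROI 1 into s×s cells and keep those sufficiently covered.

    Tiling is anchored at the top-left corner of the mask's bounding box.
    A cell is retained when (pixels inside ROI 1) / s² >= ``min_coverage``;
    cells clipped by the image border keep the full s² denominator.
    """
    roi = mask if isinstance(mask, ROIMask) else ROIMask(mask)
    if roi.is_empty:
        raise ValueError("ROI 1 mask is empty")
    if cell_side < 4:
        raise ValueError("cell_side must be >= 4 px")
    m = roi.mask
    rows_any = np.flatnonzero(m.any(axis=1))
    cols_any = np.flatnonzero(m.any(axis=0))
    r_min, r_max = rows_any[0], rows_any[-1]
    c_min, c_max = cols_any[0], cols_any[-1]

    cells: list[GridCell] = []
    cell_id = 0
    for gi, r0 in enumerate(range(r_min, r_max + 1, cell_side)):
        for gj, c0 in enumerate(range(c_min, c_max + 1, cell_side)):
            r1 = min(r0 + cell_side, m.shape[0])
            c1 = min(c0 + cell_side, m.shape[1])
            inside = m[r0:r1, c0:c1]
            coverage = inside.sum() / cell_side**2
            if coverage >= min_coverage:
                rr, cc = np.nonzero(inside)
                cell = GridCell(cell_id, r0, r1, c0, c1, rr + r0, cc + c0)
                cell._grid_index = (gi, gj)
                cells.append(cell)
                cell_id += 1
    if not cells:
        raise ValueError(
            f"no grid cell reaches coverage {min_coverage} at cell_side "
            f"{cell_side}; try a smaller cell_side"
        )
    return SubregionGrid(cell_side, min_coverage, cells, roi)


@dataclass
class TICCurve:
    """Per-region intensity-versus-time series (times relative to injection)."""

    times: np.ndarray
    intensities: np.ndarray
    region_id: str = ""
    baseline: float = 0.0
    preprocessed: bool = False
    baseline_window: tuple[float, float] | None = None
    smoothing_window: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


def extract_tic(video: VideoSequence, region) -> TICCurve:
    """Mean pixel intensity of a region at each frame.

    ``region`` is an :class:`ROIMask`, a boolean array, or a
    :class:`GridCell` (whose ROI-interior pixels are used).
    """
    if isinstance(region, GridCell):
        rows, cols, rid = region.rows, region.cols, f"cell{region.cell_id}"
    else:
        m = region.mask if isinstance(region, ROIMask) else np.asarray(region, bool)
        if m.shape != video.frame_shape:
            raise ValueError("region shape does not match the video frames")
        rows, cols = np.nonzero(m)
        rid = getattr(region, "role", "region")
    if rows.size == 0:
        raise ValueError("region is empty")
    flat = video.frames.reshape(video.n_frames, -1)
    idx = rows * video.frame_shape[1] + cols
    intensities = flat[:, idx].mean(axis=1, dtype=float)
    return TICCurve(video.times_post_injection(), intensities, region_id=rid)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return np.asarray(values, dtype=float).copy()
    half = window // 2
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def preprocess_tic(
    curve: TICCurve,
    baseline_window: tuple[float, float] = (-5.0, 0.0),
    smoothing_window: int = 1,
) -> TICCurve:
    """Baseline-subtract and smooth a raw TIC.

    The baseline is the mean intensity over frames whose time falls inside
    ``baseline_window`` (s, injection-relative; the window must precede
    enhancement onset).  Intensities become the centered moving average of
    (raw − baseline), clipped at 0 from below.
    """
    t_a, t_b = baseline_window
    sel = (curve.times >= t_a) & (curve.times <= t_b)
    if not sel.any():
        raise ValueError(
            f"baseline window [{t_a}, {t_b}] s contains no samples "
            f"(curve support [{curve.times[0]}, {curve.times[-1]}] s)"
        )
    baseline = float(curve.intensities[sel].mean())
    corrected = moving_average(curve.intensities - baseline, smoothing_window)
    np.clip(corrected, 0.0, None, out=corrected)
    return TICCurve(
        curve.times.copy(),
        corrected,
        region_id=curve.region_id,
        baseline=baseline,
        preprocessed=True,
        baseline_window=(t_a, t_b),
        smoothing_window=smoothing_window,
    )


@dataclass
class TICFeatures:
    """The five-parameter TIC summary; ``rpd`` is NaN when the parenchymal
    peak is zero (flagged missing, never infinity)."""

    ttp_s: float
    pi: float
    auc: float
    pd: float
    rpd: float

    def to_array(self) -> np.ndarray:
        return np.array([self.ttp_s, self.pi, self.auc, self.pd, self.rpd])

    @property
    def rpd_defined(self) -> bool:
        return bool(np.isfinite(self.rpd))


def tic_features(
    mass_curve: TICCurve, parenchyma_curve: TICCurve, t_end: float = 90.0
) -> TICFeatures:
    """Compute (TTP, PI, AUC, PD, RPD) of a mass TIC against parenchyma.

    Both curves must be preprocessed with identical settings.  The peak is
    the discrete maximum on [0, t_end]; ties resolve to the first occurrence.
    AUC is the trapezoidal integral of the mass curve on the same window.
    PD = PI_mass − PI_parenchyma; RPD = PD / PI_parenchyma.
    """
    for c in (mass_curve, parenchyma_curve):
        if not c.preprocessed:
            raise ValueError("curves must be preprocessed (baseline-subtracted)")
    if (
        mass_curve.baseline_window != parenchyma_curve.baseline_window
        or mass_curve.smoothing_window != parenchyma_curve.smoothing_window
    ):
        raise ValueError("mass and parenchyma curves use different preprocessing")

    def window(c: TICCurve):
        sel = (c.times >= 0) & (c.times <= t_end)
        if not sel.any():
            raise ValueError("curve has no samples in [0, t_end]")
        return c.times[sel], c.intensities[sel]

    t_m, y_m = window(mass_curve)
    t_p, y_p = window(parenchyma_curve)
    i_peak = int(np.argmax(y_m))  # argmax returns the first maximum
    pi_mass = float(y_m[i_peak])
    ttp = float(t_m[i_peak])
    auc = float(np.trapezoid(y_m, t_m))
    pi_paren = float(y_p.max())
    pd_ = pi_mass - pi_paren
    rpd = pd_ / pi_paren if pi_paren > 0 else float("nan")
    return TICFeatures(ttp_s=ttp, pi=pi_mass, auc=auc, pd=pd_, rpd=rpd)


def features_per_cell(
    video: VideoSequence,
    grid: SubregionGrid,
    parenchyma_mask: ROIMask,
    baseline_window: tuple[float, float] = (-5.0, 0.0),
    smoothing_window: int = 1,
    t_end: float = 90.0,
):
    """Five-parameter features for every grid cell against the ROI 2 reference.

    Returns a pandas DataFrame with columns ``cell_id, ttp_s, pi, auc, pd,
    rpd``, one row per cell.
    """
    import pandas as pd

    paren = preprocess_tic(
        extract_tic(video, parenchyma_mask), baseline_window, smoothing_window
    )
    records = []
    for cell in grid.cells:
        curve = preprocess_tic(
            extract_tic(video, cell), baseline_window, smoothing_window
        )
        f = tic_features(curve, paren, t_end=t_end)
        records.append(
            {
                "cell_id": cell.cell_id,
                "ttp_s": f.ttp_s,
                "pi": f.pi,
                "auc": f.auc,
                "pd": f.pd,
                "rpd": f.rpd,
            }
        )
    return pd.DataFrame.from_records(records)
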