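"""Thermogram overlay and FNA-target suggestion.

The per-subregion calls are rendered as a false-color overlay on a CH-EUS
frame — red for cancerous, blue for noncancerous, gray for necrosis — and
the suggested fine-needle-aspiration target is the centroid of the largest
4-connected block of cancerous cells, so the needle avoids necrotic
(non-enhancing) and inflammatory (iso/hyperenhanced) tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classifier import SubregionResult
from .tic import SubregionGrid

LABEL_COLORS: dict[str, tuple[int, int, int]] = {
    "cancerous": (220, 20, 60),
    "noncancerous": (30, 100, 220),
    "necrosis": (128, 128, 128),
}


def render_thermogram(
    grid: SubregionGrid,
    results: list[SubregionResult],
    base_frame: np.ndarray,
    alpha: float = 0.5,
    colors: dict[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Blend per-cell label colors into the base frame; returns uint8 RGB.

    Each cell's ROI-interior pixels are tinted with its label color at
    opacity ``alpha``; pixels outside all cells are unchanged.  Every grid
    cell must have a result.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    colors = colors or LABEL_COLORS
    by_cell = {r.cell_id: r for r in results}
    missing = [c.cell_id for c in grid.cells if c.cell_id not in by_cell]
    if missing:
        raise ValueError(f"missing results for cells {missing}")

    base = np.asarray(base_frame, dtype=float)
    if base.ndim == 2:
        lo, hi = base.min(), base.max()
        scaled = (base - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(base)
        rgb = np.stack([scaled] * 3, axis=-1)
    else:
        rgb = base[..., :3].copy()
    for cell in grid.cells:
        color = np.asarray(colors[by_cell[cell.cell_id].label], dtype=float)
        rgb[cell.rows, cell.cols] = (
            (1.0 - alpha) * rgb[cell.rows, cell.cols] + alpha * color
        )
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


@dataclass
class FNATarget:
    """Suggested puncture point (pixel coordinates, row/col)."""

    row: float
    col: float
    component_cells: int
    mean_confidence: float
    status: str = "ok"


NO_TARGET = FNATarget(float("nan"), float("nan"), 0, float("nan"), status="no target")


def suggest_fna_target(
    grid: SubregionGrid, results: list[SubregionResult]
) -> FNATarget:
    """Target the centroid of the largest 4-connected cancerous component.

    Ties in component size break by higher mean confidence, then by the
    component containing the top-left-most cell.  If the centroid of an
    irregular component falls outside its cells, the nearest member-cell
    center is used instead, so the target always lies inside a cancerous
    cell.  With no cancerous cell, a structured "no target" result is
    returned.
    """
    by_cell = {r.cell_id: r for r in results}
    cancerous = [c for c in grid.cells if by_cell[c.cell_id].label == "cancerous"]
    if not cancerous:
        return NO_TARGET

    gi = np.array([c.grid_index for c in cancerous])
    occ_shape = gi.max(axis=0) + 1
    occ = np.zeros(occ_shape, dtype=bool)
    occ[gi[:, 0], gi[:, 1]] = True
    labeled, n = ndimage.label(occ)  # default structure = 4-connectivity

    components = []
    for lab in range(1, n + 1):
        cells = [c for c, g in zip(cancerous, gi) if labeled[g[0], g[1]] == lab]
        mean_conf = float(np.mean([by_cell[c.cell_id].confidence for c in cells]))
        top_left = min((c.row0, c.col0) for c in cells)
        components.append((len(cells), mean_conf, top_left, cells))
    # size desc, confidence desc, then top-left-most cell
    components.sort(key=lambda t: (-t[0], -t[1], t[2]))
    size, mean_conf, _, cells = components[0]

    centers = np.array([c.center for c in cells])
    centroid = centers.mean(axis=0)
    inside = any(
        c.row0 <= centroid[0] < c.row1 and c.col0 <= centroid[1] < c.col1
        for c in cells
    )
    if not inside:
        centroid = centers[np.argmin(np.linalg.norm(centers - centroid, axis=1))]
    return FNATarget(float(centroid[0]), float(centroid[1]), size, mean_conf)
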