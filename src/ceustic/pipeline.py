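"""End-to-end orchestration: stabilize → ROI → subdivide → TIC → classify →
aggregate → thermogram.

Driven by a YAML config (see :func:`run_pipeline`); every stage logs its
parameters and timing, and all outputs (per-cell CSV, diagnosis JSON,
thermogram PNG, motion-model CSV) land in the configured output directory.
One seed in the config fans out deterministically to every stochastic
stage, so the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import classifier as clf
from . import io as cio
from . import segmentation as seg
from . import stabilization as stab
from . import thermogram as thermo
from . import tic as ctic

log = logging.getLogger(__name__)

EXIT_CODES = {"benign": 0, "malignant": 2, "no mass": 3, "non-enhancing mass": 4}

_REQUIRED = ("video", "model", "out_dir")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise StageError("config", "config must be a mapping")
    for key in _REQUIRED:
        if key not in config:
            raise StageError("config", f"missing required field '{key}'")
    return config


def run_pipeline(config) -> dict:
    """Run the full diagnosis pipeline from a YAML config (path or dict).

    Required config fields: ``video`` (frame stack path), ``model`` (trained
    classifier path) and ``out_dir``.  Optional: ``roi`` (``mass_mask`` /
    ``parenchyma_mask`` paths; baseline segmenter is used when no mass mask
    is given), ``stabilize`` (``enabled``, ``window``), ``tic``
    (``cell_side``, ``min_coverage``, ``baseline_window``,
    ``smoothing_window``, ``t_end``), ``necrosis_fraction`` (default 0.05 of
    the parenchymal peak) and ``seed``.

    Returns a report dict whose ``status`` is one of ``benign``,
    ``malignant``, ``no mass`` or ``non-enhancing mass``.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"config": {k: str(v) for k, v in cfg.items()}, "stages": {}}

    def stage(name):
        log.info("stage %s: start", name)
        return time.perf_counter()

    def done(name, t0, **params):
        # timings go to the log only, so written reports are byte-stable
        dt = time.perf_counter() - t0
        report["stages"][name] = dict(params)
        log.info("stage %s: done in %.3f s %s", name, dt, params or "")

    # --- read ---------------------------------------------------------------
    t0 = stage("read")
    try:
        video = cio.read_video(cfg["video"])
    except (OSError, ValueError) as exc:
        raise StageError("read", str(exc), "check the video path and its sidecar YAML")
    done("read", t0, n_frames=video.n_frames, frame_shape=list(video.frame_shape))

    # --- stabilize ----------------------------------------------------------
    stab_cfg = cfg.get("stabilize", {}) or {}
    if stab_cfg.get("enabled", True) and video.n_frames >= 2:
        t0 = stage("stabilize")
        window = int(stab_cfg.get("window", 15))
        video, motion = stab.stabilize(video, window=window)
        motion.to_dataframe().to_csv(out_dir / "motion.csv", index=False)
        done("stabilize", t0, window=window)

    # --- ROI ----------------------------------------------------------------
    roi_cfg = cfg.get("roi", {}) or {}
    t0 = stage("segment")
    paren_mask = None
    if roi_cfg.get("parenchyma_mask"):
        paren_mask = cio.read_mask(roi_cfg["parenchyma_mask"], role="parenchyma")
    if roi_cfg.get("mass_mask"):
        external = cio.read_mask(roi_cfg["mass_mask"], role="mass")
        result = seg.segment_mass(
            None, method="external-mask", external_mask=external
        )
    else:
        result = seg.segment_mass(
            video, method="baseline", reference_mask=paren_mask
        )
    if not result.detected:
        report["status"] = "no mass"
        cio.write_report(report, out_dir / "diagnosis.json")
        return report
    mass_mask = result.mask
    done("segment", t0, roi1_pixels=mass_mask.n_pixels)
    if paren_mask is None:
        raise StageError(
            "segment",
            "no parenchymal reference (ROI 2) available",
            "provide roi.parenchyma_mask in the config",
        )

    # --- TIC ----------------------------------------------------------------
    tic_cfg = cfg.get("tic", {}) or {}
    t0 = stage("tic")
    cell_side = int(tic_cfg.get("cell_side", 32))
    grid = ctic.subdivide_roi(
        mass_mask, cell_side, float(tic_cfg.get("min_coverage", 0.5))
    )
    baseline_window = tuple(tic_cfg.get("baseline_window", (-5.0, 0.0)))
    smoothing_window = int(tic_cfg.get("smoothing_window", 1))
    t_end = float(tic_cfg.get("t_end", 90.0))
    cells = ctic.features_per_cell(
        video, grid, paren_mask, baseline_window, smoothing_window, t_end
    )
    cells.to_csv(out_dir / "cells.csv", index=False)
    paren_curve = ctic.preprocess_tic(
        ctic.extract_tic(video, paren_mask), baseline_window, smoothing_window
    )
    paren_pi = float(paren_curve.intensities.max())
    done("tic", t0, n_cells=len(grid), cell_side=cell_side, parenchyma_pi=paren_pi)

    # --- classify -----------------------------------------------------------
    t0 = stage("classify")
    model = clf.RFModel.load(cfg["model"])
    necrosis_threshold = float(cfg.get("necrosis_fraction", 0.05)) * paren_pi
    results = clf.predict_subregions(model, cells, necrosis_threshold)
    try:
        diagnosis = clf.aggregate_mass(results)
    except ValueError:
        report["status"] = "non-enhancing mass"
        cio.write_report(report, out_dir / "diagnosis.json")
        return report
    done("classify", t0, necrosis_threshold=necrosis_threshold, seed=seed)

    # --- thermogram ---------------------------------------------------------
    t0 = stage("thermogram")
    base_frame = video.frames[video.n_frames // 2]
    overlay = thermo.render_thermogram(grid, results, base_frame, alpha=0.5)
    iio.imwrite(out_dir / "thermogram.png", overlay)
    target = thermo.suggest_fna_target(grid, results)
    done("thermogram", t0)

    report["status"] = diagnosis.call
    report["diagnosis"] = {
        "call": diagnosis.call,
        "average_confidence": diagnosis.average_confidence,
        "n_cells_used": diagnosis.n_cells_used,
        "n_necrotic": diagnosis.n_necrotic,
    }
    report["fna_target"] = {
        "row": target.row,
        "col": target.col,
        "component_cells": target.component_cells,
        "mean_confidence": target.mean_confidence,
        "status": target.status,
    }
    report["subregions"] = [
        {"cell_id": r.cell_id, "label": r.label, "confidence": r.confidence}
        for r in results
    ]
    cio.write_report(report, out_dir / "diagnosis.json")
    return report
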