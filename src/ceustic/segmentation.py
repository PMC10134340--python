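"""Mass-ROI acquisition: pluggable segmenters, post-filters, IoU evaluation.

The production-grade mass segmenter in a clinical deployment is a trained
deep network; this module fixes the *interface* and the *evaluation
protocol* so any segmenter plugs in, and ships a classical baseline that
exploits the defining perfusion property of pancreatic adenocarcinoma —
hypoenhancement relative to parenchyma throughout the contrast phases — so
the end-to-end pipeline is testable on phantoms.

Every candidate mask, whatever its source, passes the same post-filters:
connected components with confidence < 0.50 are removed, and components of
20 pixels or fewer are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label
from skimage.morphology import closing, disk

from .io import ROIMask, VideoSequence

CONFIDENCE_THRESHOLD = 0.50
MIN_COMPONENT_PIXELS = 20  # components must exceed this pixel count


@dataclass
class ComponentInfo:
    label: int
    area: int
    confidence: float
    kept: bool


@dataclass
class SegmentationResult:
    """Post-filtered segmentation outcome.

    ``mask`` is the designated ROI 1 (largest surviving component; empty
    when nothing survives), ``components`` lists every candidate component
    with its confidence and filter outcome, and ``status`` is ``"ok"`` or
    ``"no mass detected"``.
    """

    mask: ROIMask
    components: list[ComponentInfo]
    status: str

    @property
    def detected(self) -> bool:
        return self.status == "ok"


def apply_post_filters(
    labeled: np.ndarray,
    confidences: dict[int, float],
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    min_pixels: int = MIN_COMPONENT_PIXELS,
) -> SegmentationResult:
    """Confidence (>= 0.50 kept) and area (> 20 px kept) component filters.

    The two filters are independent per component, so their application
    order is immaterial.  The largest surviving component becomes ROI 1;
    all components are reported.
    """
    components: list[ComponentInfo] = []
    survivors: list[tuple[int, int]] = []
    for lab in np.unique(labeled):
        if lab == 0:
            continue
        area = int((labeled == lab).sum())
        conf = float(confidences.get(int(lab), 1.0))
        kept = conf >= confidence_threshold and area > min_pixels
        components.append(ComponentInfo(int(lab), area, conf, kept))
        if kept:
            survivors.append((area, int(lab)))
    if not survivors:
        empty = ROIMask(np.zeros(labeled.shape, dtype=bool), role="mass",
                        source="segmenter")
        return SegmentationResult(empty, components, "no mass detected")
    survivors.sort(reverse=True)
    roi1 = ROIMask(labeled == survivors[0][1], role="mass", source="segmenter")
    return SegmentationResult(roi1, components, "ok")


def segment_mass(
    video_or_frame,
    method: str = "baseline",
    external_mask: ROIMask | np.ndarray | None = None,
    external_confidence: float = 1.0,
    reference_mask: ROIMask | np.ndarray | None = None,
    window: tuple[float, float] = (10.0, 90.0),
    threshold_ratio: float = 0.85,
    closing_radius: int = 2,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    min_pixels: int = MIN_COMPONENT_PIXELS,
) -> SegmentationResult:
    """Segment the mass region (ROI 1) and apply the post-filters.

    ``method="baseline"`` thresholds the temporal-mean enhancement image over
    ``window`` (s post-injection) at ``threshold_ratio`` times a parenchymal
    reference level (the median over ``reference_mask`` when supplied, else
    the image median — parenchyma dominates the field of view), applies
    morphological closing, and scores each component's confidence as the
    fraction of its pixels below threshold before closing.

    ``method="external-mask"`` routes a supplied mask (e.g. from a trained
    network or manual annotation) through the same post-filters with
    ``external_confidence`` per component.
    """
    if method == "external-mask":
        if external_mask is None:
            raise ValueError("external-mask method requires external_mask")
        m = external_mask.mask if isinstance(external_mask, ROIMask) else np.asarray(
            external_mask, bool
        )
        labeled = _cc_label(m, connectivity=2)
        confs = {int(l): external_confidence for l in np.unique(labeled) if l != 0}
        return apply_post_filters(labeled, confs, confidence_threshold, min_pixels)

    if method != "baseline":
        raise ValueError(f"unknown segmentation method {method!r}")
    if not isinstance(video_or_frame, VideoSequence):
        raise ValueError("baseline method requires a VideoSequence")
    video = video_or_frame
    t = video.times_post_injection()
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError(f"no frames in enhancement window {window}")
    mean_img = video.frames[sel].astype(float).mean(axis=0)

    if reference_mask is not None:
        ref_m = (
            reference_mask.mask
            if isinstance(reference_mask, ROIMask)
            else np.asarray(reference_mask, bool)
        )
        reference = float(np.median(mean_img[ref_m]))
    else:
        reference = float(np.median(mean_img))
    if reference <= 0:
        raise ValueError("non-positive parenchymal reference level")

    hypo = mean_img < threshold_ratio * reference
    closed = closing(hypo, disk(closing_radius))
    labeled = _cc_label(closed, connectivity=2)
    confs = {}
    for lab in np.unique(labeled):
        if lab == 0:
            continue
        comp = labeled == lab
        confs[int(lab)] = float(hypo[comp].mean())
    return apply_post_filters(labeled, confs, confidence_threshold, min_pixels)


def iou(mask_a: ROIMask | np.ndarray, mask_b: ROIMask | np.ndarray) -> float:
    """Intersection-over-union (overlap rate) of two same-shape masks.

    Two empty masks have IoU 0 by convention (with a warning).
    """
    a = mask_a.mask if isinstance(mask_a, ROIMask) else np.asarray(mask_a, bool)
    b = mask_b.mask if isinstance(mask_b, ROIMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty; IoU defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def evaluate_segmentation(
    predicted: list, truth: list, iou_threshold: float = 0.50
) -> tuple[float, float]:
    """Mean IoU over mask pairs and accuracy at an IoU threshold.

    A pair counts as correct when IoU >= ``iou_threshold`` (closed boundary:
    exactly-at-threshold counts as success).
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"paired lists differ in length: {len(predicted)} vs {len(truth)}"
        )
    if not predicted:
        raise ValueError("need at least one mask pair")
    scores = np.array([iou(p, t) for p, t in zip(predicted, truth)])
    return float(scores.mean()), float((scores >= iou_threshold).mean())
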