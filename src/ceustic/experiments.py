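"""Reference end-to-end experiments on phantom cohorts.

These are the package's standard self-checks, shared by the test suite and
the reproduction script: the TIC analytic oracle, the stabilization
jitter-reduction experiment, and mass-level classification accuracy on a
phantom cohort with a stratified 8:2 split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classifier as clf
from . import phantom as ph
from . import segmentation as seg
from . import stabilization as stab
from . import tic as ctic

# Compact study-condition phantom used by the cohort experiments: 80x80 px,
# ~4 grid cells per mass at cell side 16, full 90 s at 5 frames/s.
COHORT_BASE_SPEC = ph.PhantomSpec(
    shape=(80, 80),
    mass_center=(44.0, 44.0),
    mass_axes=(18.0, 13.0),
    parenchyma_box=(4, 24, 4, 24),
    sigma_speckle=0.1,
)


def tic_oracle(seed: int = 0) -> dict:
    """Extract TIC features from a noiseless, motionless phantom and compare
    with the analytic bolus values (peak at t0 + tp, height A, closed-form
    AUC)."""
    cls = ph.PerfusionClass("mass", amplitude=100.0, t0=10.0, tp=15.0,
                            alpha=2.0, baseline=5.0)
    classes = dict(ph.DEFAULT_CLASSES)
    classes["cancerous"] = cls
    spec = ph.PhantomSpec(
        shape=(64, 64), mass_center=(32.0, 32.0), mass_axes=(14.0, 10.0),
        parenchyma_box=(4, 20, 4, 20), classes=classes, sigma_speckle=0.0,
    )
    video, masks, _, _ = ph.render_phantom(spec, seed=seed)
    mass = ctic.preprocess_tic(
        ctic.extract_tic(video, masks["mass"]), baseline_window=(0.0, 5.0)
    )
    paren = ctic.preprocess_tic(
        ctic.extract_tic(video, masks["parenchyma"]), baseline_window=(0.0, 5.0)
    )
    feats = ctic.tic_features(mass, paren, t_end=90.0)
    analytic_auc = ph.gamma_variate_auc(cls, 90.0)
    return {
        "ttp_s": feats.ttp_s,
        "pi": feats.pi,
        "auc_trapezoid": feats.auc,
        "auc_analytic": analytic_auc,
        "auc_rel_err": abs(feats.auc - analytic_auc) / analytic_auc,
        "frame_interval_s": 1.0 / spec.fps,
    }


def stabilization_experiment(
    seed: int = 0,
    sigma_translation: float = 3.0,
    n_frames: int = 120,
    window: int = 61,
) -> dict:
    """Jitter a textured phantom with random-walk translation and measure the
    RMS frame-to-frame displacement before and after stabilization (phase
    correlation, independent of the tracking pipeline).

    The 160-px field keeps the accumulated random-walk excursion
    (~sigma * sqrt(T) px) inside the image so corners remain trackable.
    """
    spec = ph.PhantomSpec(
        shape=(160, 160), mass_center=(80.0, 80.0), mass_axes=(30.0, 22.0),
        parenchyma_box=(8, 48, 8, 48), sigma_speckle=0.4,
        duration=(n_frames - 1) / 5.0,
    )
    video, _, _, _ = ph.render_phantom(spec, seed=seed)
    jittered, _ = ph.apply_jitter(
        video, ph.MotionSpec(sigma_translation=sigma_translation), seed=seed + 1
    )
    stabilized, _ = stab.stabilize(jittered, window=window)
    rms_before = stab.frame_displacement_rms(jittered)
    rms_after = stab.frame_displacement_rms(stabilized)
    return {
        "rms_before_px": rms_before,
        "rms_after_px": rms_after,
        "residual_ratio": rms_after / rms_before,
        "n_frames": n_frames,
    }


def phantom_cohort_features(
    n_benign: int = 100,
    n_malignant: int = 100,
    seed: int = 0,
    base_spec: ph.PhantomSpec | None = None,
    cell_side: int = 16,
):
    """Render a phantom cohort and extract per-cell TIC features per mass.

    Returns ``(per_mass, labels)`` where ``per_mass`` is a list of per-cell
    feature DataFrames (one per mass, truth masks used for the ROIs) and
    ``labels`` the mass-level truth array.
    """
    base = base_spec or COHORT_BASE_SPEC
    cohort = ph.sample_phantom_cohort(n_benign, n_malignant, base_spec=base, seed=seed)
    rng = np.random.default_rng(seed)
    per_mass, labels = [], []
    for spec, label in cohort:
        video, masks, _, _ = ph.render_phantom(spec, seed=int(rng.integers(2**31)))
        grid = ctic.subdivide_roi(masks["mass"], cell_side=cell_side)
        cells = ctic.features_per_cell(
            video, grid, masks["parenchyma"], baseline_window=(0.0, 5.0)
        )
        per_mass.append(cells)
        labels.append(label)
    return per_mass, np.asarray(labels)


def mass_level_accuracy(
    per_mass: list[pd.DataFrame],
    labels: np.ndarray,
    seed: int = 0,
    necrosis_threshold: float = 5.0,
    permute_labels: bool = False,
):
    """Stratified 8:2 split at mass level, subregion-labeled forest training,
    and mass-level held-out accuracy via confidence aggregation.

    With ``permute_labels`` the mass labels are randomly permuted first (the
    label-permutation null).  Returns ``(accuracy, n_test)``.
    """
    labels = np.asarray(labels)
    if permute_labels:
        labels = labels.copy()
        np.random.default_rng(seed).shuffle(labels)
    train_idx, test_idx = clf.split_dataset(labels, seed=seed)
    X_train = pd.concat([per_mass[i] for i in train_idx], ignore_index=True)
    y_train = np.concatenate(
        [[labels[i]] * len(per_mass[i]) for i in train_idx]
    )
    model = clf.train_rf(X_train, y_train, seed=seed)
    correct = 0
    for i in test_idx:
        results = clf.predict_subregions(model, per_mass[i], necrosis_threshold)
        call = clf.aggregate_mass(results).call
        correct += call == labels[i]
    return correct / len(test_idx), len(test_idx)


def segmentation_experiment(n_masses: int = 20, seed: int = 0) -> dict:
    """Baseline-segment a noiseless phantom cohort against truth masks and
    report the mean IoU and accuracy at the 0.50 overlap threshold.

    Geometry varies between masses; kinetics stay at the class defaults so
    the experiment probes mass localization, not enhancement-threshold
    margins.
    """
    base = ph.PhantomSpec(
        shape=(96, 96), mass_center=(52.0, 52.0), mass_axes=(20.0, 15.0),
        parenchyma_box=(4, 28, 4, 28), sigma_speckle=0.0,
    )
    cohort = ph.sample_phantom_cohort(
        0, n_masses, base_spec=base, seed=seed, kinetic_jitter=0.0
    )
    predicted, truth = [], []
    for spec, _ in cohort:
        video, masks, _, _ = ph.render_phantom(spec, seed=seed)
        result = seg.segment_mass(video, reference_mask=masks["parenchyma"])
        predicted.append(result.mask)
        truth.append(masks["mass"])
    mean_iou, acc = seg.evaluate_segmentation(predicted, truth, iou_threshold=0.50)
    return {"mean_iou": mean_iou, "accuracy_at_0.5": acc, "n": n_masses}
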