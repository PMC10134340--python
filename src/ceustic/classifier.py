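"""Random-forest benign/malignant classification of TIC feature vectors.

Each mass subregion contributes one five-parameter vector (TTP, PI, AUC,
PD, RPD).  Subregions inherit their mass-level label during training
(per-subregion pathology does not exist — a known source of label noise).
At prediction time non-enhancing subregions (PI below the necrosis
threshold) are set aside as necrosis; the remaining cells receive a
malignancy probability, and the mass-level call is the unweighted mean
confidence over non-necrotic cells, thresholded at 0.50.  A confidence of
exactly 0.50 classifies as malignant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .tic import FEATURE_NAMES

log = logging.getLogger(__name__)

CONFIDENCE_CUT = 0.50
MODEL_FORMAT_VERSION = 1


def split_dataset(labels, test_fraction: float = 0.2, seed: int | None = None):
    """Stratified train/test index split at the 8:2 default ratio.

    Per class, ``floor((1 - test_fraction) * n)`` items go to training and
    the remainder to test, so class proportions are preserved within
    rounding.  A class with a single item goes entirely to training (with a
    warning).  Returns ``(train_idx, test_idx)`` as sorted integer arrays;
    the split is disjoint, exhaustive and seed-reproducible.
    """
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 1:
            warnings.warn(
                f"class {cls!r} has a single item; assigning it to training",
                stacklevel=2,
            )
            train.extend(idx)
            continue
        rng.shuffle(idx)
        n_train = int(np.floor((1.0 - test_fraction) * idx.size))
        n_train = max(1, n_train)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train, int)), np.sort(np.asarray(test, int))


@dataclass
class RFModel:
    """Fitted random forest plus its feature contract."""

    forest: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]
    format_version: int = MODEL_FORMAT_VERSION

    def predict_malignancy(self, features) -> np.ndarray:
        """Malignancy probability in [0, 1] per feature row."""
        X = _as_matrix(features, self.feature_names)
        proba = self.forest.predict_proba(X)
        col = list(self.forest.classes_).index("malignant")
        return proba[:, col]

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_, index=self.feature_names)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RFModel":
        model = joblib.load(path)
        if model.format_version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format {model.format_version} != {MODEL_FORMAT_VERSION}"
            )
        return model


def _as_matrix(features, names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[names].to_numpy(dtype=float)
    return np.asarray(features, dtype=float).reshape(-1, len(names))


def train_rf(
    features,
    labels,
    n_estimators: int = 500,
    max_features: int = 2,  # ~ sqrt(5) features per split
    max_depth: int | None = None,
    seed: int | None = None,
) -> RFModel:
    """Train the benign/malignant random forest on five-parameter rows.

    Rows with missing values (e.g. flagged-missing RPD) are dropped with a
    logged count.  Training is reproducible by ``seed``.
    """
    X = _as_matrix(features, FEATURE_NAMES)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    ok = np.all(np.isfinite(X), axis=1)
    if not ok.all():
        log.info("dropping %d rows with missing feature values", (~ok).sum())
    X, y = X[ok], y[ok]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires both benign and malignant samples")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        max_depth=max_depth,
        random_state=None if seed is None else int(seed) % (2**32),
        n_jobs=1,
    )
    forest.fit(X, y)
    return RFModel(forest, list(FEATURE_NAMES), [str(c) for c in classes])


@dataclass
class SubregionResult:
    """Per-cell call: cancerous / noncancerous / necrosis.

    Non-necrotic cells carry a malignancy confidence and are cancerous iff
    confidence >= 0.50; necrotic cells carry no confidence.
    """

    cell_id: int
    label: str
    confidence: float | None
    features: pd.Series | None = field(default=None, repr=False)


def predict_subregions(
    model: RFModel,
    cell_features: pd.DataFrame,
    necrosis_threshold: float,
) -> list[SubregionResult]:
    """Classify every grid cell, flagging non-enhancing cells as necrosis.

    ``cell_features`` must contain ``cell_id`` plus the five feature
    columns.  Cells with PI below ``necrosis_threshold`` (a.u.; typically 5%
    of the parenchymal peak) are labeled necrosis and excluded from
    classification.
    """
    if necrosis_threshold < 0:
        raise ValueError("necrosis_threshold must be >= 0")
    results: list[SubregionResult] = []
    enhancing = cell_features[cell_features["pi"] >= necrosis_threshold]
    confidences = {}
    if len(enhancing):
        feats = enhancing[FEATURE_NAMES].copy()
        if feats["rpd"].isna().any():
            log.warning(
                "imputing rpd=0 for %d enhancing cells with undefined RPD",
                int(feats["rpd"].isna().sum()),
            )
            feats["rpd"] = feats["rpd"].fillna(0.0)
        probs = model.predict_malignancy(feats)
        confidences = dict(zip(enhancing["cell_id"].to_numpy(), probs))
    for _, row in cell_features.iterrows():
        cid = int(row["cell_id"])
        if cid in confidences:
            conf = float(confidences[cid])
            label = "cancerous" if conf >= CONFIDENCE_CUT else "noncancerous"
            results.append(SubregionResult(cid, label, conf, row[FEATURE_NAMES]))
        else:
            results.append(SubregionResult(cid, "necrosis", None, row[FEATURE_NAMES]))
    return results


@dataclass
class MassDiagnosis:
    """Mass-level call aggregated over subregions."""

    average_confidence: float
    call: str  # "malignant" | "benign"
    n_cells_used: int
    n_necrotic: int


def aggregate_mass(results: list[SubregionResult]) -> MassDiagnosis:
    """Unweighted mean malignancy confidence over non-necrotic cells.

    The mass is called malignant iff the average confidence >= 0.50.
    Raises when every cell is necrotic (mass entirely non-enhancing).
    """
    confs = [r.confidence for r in results if r.label != "necrosis"]
    n_necrotic = sum(1 for r in results if r.label == "necrosis")
    if not confs:
        raise ValueError("mass entirely non-enhancing: no classifiable subregion")
    avg = float(np.mean(confs))
    call = "malignant" if avg >= CONFIDENCE_CUT else "benign"
    return MassDiagnosis(avg, call, len(confs), n_necrotic)
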