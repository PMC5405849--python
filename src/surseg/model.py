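"""Semi-supervised region classification from sparse annotations.

A probabilistic classifier is trained on the annotated regions only and
then predicts label probabilities for every region.  The default is an
extremely randomized forest (ERF), which needs no parameter tuning and is
robust to heterogeneous descriptor scales; random forest, gradient
boosting, SVM (with probability calibration, slower) and SGD-optimised
logistic regression are available as alternatives.  Annotation strokes are
tiny compared to the volume, so classes are weighted by inverse frequency.

The classifier's per-region confidence (maximum class probability) drives
the iterative workflow: confident predictions can be *accepted* as new
annotations and the model retrained, growing the training set
monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import SGDClassifier
from sklearn.svm import SVC

from .descriptors import DescriptorMatrix
from .superregions import SupervoxelPartition

__all__ = [
    "TrainedModel",
    "ProbabilityField",
    "train",
    "predict",
    "confidence_map",
    "accept_by_confidence",
]


@dataclass
class ProbabilityField:
    """Per-region class probabilities; rows sum to 1."""

    probs: np.ndarray
    label_ids: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.label_ids = np.asarray(self.label_ids)
        if self.probs.shape[1] != self.label_ids.size:
            raise ValueError("column count must match label_ids")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def argmax_labels(self) -> np.ndarray:
        """Raw (pre-refinement) labelling: most probable label per region."""
        return self.label_ids[np.argmax(self.probs, axis=1)]


@dataclass
class TrainedModel:
    clf: object
    label_ids: np.ndarray
    n_features: int
    classifier_kind: str


def _make_classifier(kind: str, hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    if kind == "erf":
        return ExtraTreesClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_features=hp.pop("max_features", "sqrt"),
            class_weight=hp.pop("class_weight", "balanced"),
            random_state=seed, **hp)
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_features=hp.pop("max_features", "sqrt"),
            class_weight=hp.pop("class_weight", "balanced"),
            random_state=seed, **hp)
    if kind == "gbm":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if kind == "svm":
        # probability calibration makes this noticeably slower than ERF
        from sklearn.calibration import CalibratedClassifierCV
        svc = SVC(class_weight=hp.pop("class_weight", "balanced"),
                  random_state=seed, **hp)
        return CalibratedClassifierCV(svc, ensemble=False, cv=3)
    if kind == "linear":
        return SGDClassifier(loss="log_loss",
                             class_weight=hp.pop("class_weight", "balanced"),
                             random_state=seed, **hp)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _unpack_annotations(ann) -> tuple[np.ndarray, np.ndarray]:
    """Accept a dict region->label or a region-length array with -1 unlabelled."""
    if isinstance(ann, dict):
        ids = np.fromiter(ann.keys(), dtype=np.int64)
        labels = np.fromiter(ann.values(), dtype=np.int64)
        return ids, labels
    ann = np.asarray(ann)
    ids = np.flatnonzero(ann >= 0)
    return ids, ann[ids]


def train(desc: DescriptorMatrix, ann, classifier_kind: str = "erf",
          hyperparams: dict | None = None, seed: int = 0) -> TrainedModel:
    """Fit a probabilistic classifier on the annotated regions only.

    ``ann`` is either a mapping ``region id -> label id`` or an array of
    length ``n_regions`` with ``-1`` marking unlabelled regions.  At least
    two distinct labels must be annotated.
    """
    ids, labels = _unpack_annotations(ann)
    if ids.size == 0:
        raise ValueError("empty annotations")
    if ids.min() < 0 or ids.max() >= desc.n_regions:
        raise ValueError("annotated region ids out of range")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 distinct annotated labels")
    clf = _make_classifier(classifier_kind, hyperparams, seed)
    clf.fit(desc.X[ids], labels)
    return TrainedModel(clf=clf, label_ids=np.asarray(clf.classes_),
                        n_features=desc.X.shape[1], classifier_kind=classifier_kind)


def predict(m: TrainedModel, desc: DescriptorMatrix) -> ProbabilityField:
    """Class probabilities for every region (annotated ones included)."""
    if desc.X.shape[1] != m.n_features:
        raise ValueError(
            f"descriptor width {desc.X.shape[1]} != training width {m.n_features}")
    probs = m.clf.predict_proba(desc.X)
    # numerical guard: renormalise tiny drift from calibrated models
    probs = probs / probs.sum(axis=1, keepdims=True)
    return ProbabilityField(probs=probs, label_ids=m.label_ids)


def confidence_map(pf: ProbabilityField,
                   p: SupervoxelPartition | None = None) -> np.ndarray:
    """Per-voxel maximum class probability, broadcast from its region.

    With ``p=None`` the field is voxel-level already and the flat confidence
    vector is returned.  Values lie in ``[1/L, 1]``.
    """
    conf = pf.probs.max(axis=1)
    if p is None:
        return conf
    if pf.probs.shape[0] != p.K:
        raise ValueError("probability rows must match supervoxel count")
    return conf[p.labels]


def accept_by_confidence(pf: ProbabilityField, threshold: float,
                         ann: np.ndarray) -> np.ndarray:
    """Accept confident predictions as new annotations.

    Regions whose maximum class probability is at least ``threshold`` and
    that are not already annotated receive their argmax label.  Existing
    annotations are never overwritten, so iterating train -> predict ->
    accept grows the annotation set monotonically.
    """
    L = pf.label_ids.size
    if not (1.0 / L < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (1/{L}, 1]")
    ann = np.asarray(ann)
    if ann.shape[0] != pf.probs.shape[0]:
        raise ValueError("annotation length must match region count")
    out = ann.copy()
    conf = pf.probs.max(axis=1)
    take = (conf >= threshold) & (ann < 0)
    out[take] = pf.argmax_labels()[take]
    return out
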