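"""Resampling of group-wise networks and leave-one-out SVM classification.

A single group yields a single network index, so classification needs a
sample of indices per group: repeatedly drop half the subjects at random
(without replacement), rebuild the group-wise network from the retained
half, and record the index — 5000 resamples per group by default.  The
resulting univariate features are classified with a linear-kernel SVM under
leave-one-out cross-validation; accuracy, sensitivity, specificity and
ROC/AUC are aggregated over the held-out predictions.  Features are
standardized inside each training fold only, so no information from the
held-out sample leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import SUVTable
from .inference import IndexFn

__all__ = ["ResampleSet", "ClassificationReport", "resample_networks", "loo_svm"]


@dataclass
class ResampleSet:
    """Index values of one group's resampled group-wise networks."""

    indices: np.ndarray
    label: str
    rate: float
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=float)
        if self.indices.size != self.n:
            raise ValueError("indices length must equal n")


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: np.ndarray  # (k, 2): false-positive rate, true-positive rate
    labels: list[str]
    roc_per_class: dict[str, np.ndarray] = field(default_factory=dict)
    y_true: np.ndarray | None = None
    scores: np.ndarray | None = None  # held-out decision scores, aligned with y_true

    def __post_init__(self) -> None:
        roc = np.asarray(self.roc, dtype=float)
        if roc.ndim != 2 or roc.shape[1] != 2:
            raise ValueError("roc must be (k, 2)")
        self.roc = roc


def resample_networks(
    group: SUVTable,
    index_fn: IndexFn,
    n: int = 5000,
    rate: float = 0.5,
    seed: int | None = None,
) -> ResampleSet:
    """Network index of ``n`` random subject subsets of one group.

    Each resample keeps ``floor(K * rate)`` distinct subjects (drawn
    without replacement) and rebuilds the group-wise network from them.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    k_keep = int(group.n_subjects * rate)
    if k_keep < 3:
        raise ValueError(
            f"floor(K * rate) = {k_keep} subjects per resample; need >= 3"
        )
    rng = np.random.default_rng(seed)
    values = np.empty(n, dtype=float)
    for it in range(n):
        rows = rng.choice(group.n_subjects, size=k_keep, replace=False)
        values[it] = index_fn(group.subset(rows))
    return ResampleSet(indices=values, label=group.group or "group", rate=rate, n=n, seed=seed)


def _binary_report(
    y: np.ndarray, pred: np.ndarray, score: np.ndarray, labels: list[str]
) -> ClassificationReport:
    pos, neg = labels[0], labels[1]
    acc = float(np.mean(pred == y))
    sens = float(np.mean(pred[y == pos] == pos))
    spec = float(np.mean(pred[y == neg] == neg))
    fpr, tpr, _ = skm.roc_curve(y, score, pos_label=pos)
    auc = float(skm.auc(fpr, tpr))
    roc = np.column_stack([fpr, tpr])
    return ClassificationReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        roc=roc, labels=labels, roc_per_class={pos: roc},
        y_true=y, scores=score,
    )


def _multiclass_report(
    y: np.ndarray, pred: np.ndarray, scores: np.ndarray,
    labels: list[str], score_order: list[str],
) -> ClassificationReport:
    acc = float(np.mean(pred == y))
    sens_per, spec_per, auc_per = [], [], []
    roc_per: dict[str, np.ndarray] = {}
    for lab in labels:
        is_lab = y == lab
        sens_per.append(float(np.mean(pred[is_lab] == lab)))
        spec_per.append(float(np.mean(pred[~is_lab] != lab)))
        col = score_order.index(lab)
        fpr, tpr, _ = skm.roc_curve(is_lab.astype(int), scores[:, col])
        roc_per[lab] = np.column_stack([fpr, tpr])
        auc_per.append(float(skm.auc(fpr, tpr)))
    return ClassificationReport(
        accuracy=acc,
        sensitivity=float(np.mean(sens_per)),
        specificity=float(np.mean(spec_per)),
        auc=float(np.mean(auc_per)),
        roc=roc_per[labels[0]],
        labels=labels,
        roc_per_class=roc_per,
        y_true=y,
        scores=scores,
    )


def loo_svm(sets: list[ResampleSet]) -> ClassificationReport:
    """Leave-one-out linear-SVM classification of univariate index features.

    For two classes the first set's label is treated as positive: the ROC
    and sensitivity refer to it.  For three classes, sensitivity,
    specificity and AUC are macro-averaged one-vs-rest.
    """
    if len(sets) < 2:
        raise ValueError("need at least two labelled groups")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be distinct")
    for s in sets:
        if s.n < 4:
            raise ValueError("need at least 4 samples per class")

    x = np.concatenate([s.indices for s in sets]).reshape(-1, 1)
    y = np.concatenate([[s.label] * s.n for s in sets])
    n_total = x.shape[0]
    multi = len(labels) > 2

    pred = np.empty(n_total, dtype=object)
    score_order: list[str] = []
    scores = np.empty((n_total, len(labels)) if multi else (n_total,), dtype=float)
    for i in range(n_total):
        train = np.ones(n_total, dtype=bool)
        train[i] = False
        scaler = StandardScaler().fit(x[train])
        clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovr")
        clf.fit(scaler.transform(x[train]), y[train])
        xt = scaler.transform(x[i : i + 1])
        pred[i] = clf.predict(xt)[0]
        dec = clf.decision_function(xt)[0]
        if multi:
            score_order = list(clf.classes_)
            scores[i] = dec
        else:
            # libsvm's decision function is signed toward classes_[1]
            scores[i] = dec if clf.classes_[1] == labels[0] else -dec

    pred = pred.astype(str)
    if multi:
        return _multiclass_report(y, pred, scores, labels, score_order)
    return _binary_report(y, pred, scores, labels)
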