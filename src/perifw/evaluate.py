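"""Classifier evaluation: confusion metrics, k-fold CV, ROC/AUC, DeLong test.

Glioblastoma is the positive class throughout: sensitivity is the recall of
glioblastomas and specificity the recall of metastases. Metrics are reported
as percentages and rounded to the nearest integer percent in tabular output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cnn import CLASSES
from .patches import PatchSet

__all__ = ["ConfusionCounts", "confusion_counts", "classification_metrics",
           "kfold_partition", "cross_validate", "CvResult",
           "RocCurve", "roc_and_auc", "delong_compare"]

logger = logging.getLogger(__name__)

POSITIVE = CLASSES[0]   # glioblastoma
NEGATIVE = CLASSES[1]   # metastasis


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with glioblastoma as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, true) -> ConfusionCounts:
    """Count TP/FP/TN/FN over paired label vectors."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    for v in (predicted, true):
        bad = set(np.unique(v)) - set(CLASSES) if v.size else set()
        if bad:
            raise ValueError(f"unknown labels {bad}")
    return ConfusionCounts(
        tp=int(((predicted == POSITIVE) & (true == POSITIVE)).sum()),
        fp=int(((predicted == POSITIVE) & (true == NEGATIVE)).sum()),
        tn=int(((predicted == NEGATIVE) & (true == NEGATIVE)).sum()),
        fn=int(((predicted == NEGATIVE) & (true == POSITIVE)).sum()),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity as percentages.

    Accuracy = (TP+TN)/(TP+TN+FP+FN); Sensitivity = TP/(TP+FN);
    Specificity = TN/(TN+FP). A metric whose denominator is zero is
    reported as None (not available), never as 0. All-zero counts raise.
    """
    if c.total == 0:
        raise ValueError("accuracy undefined for all-zero confusion counts")
    out: dict[str, float | None] = {
        "accuracy": 100.0 * (c.tp + c.tn) / c.total,
        "sensitivity": 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else None,
        "specificity": 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else None,
    }
    return out


def round_metrics(m: dict[str, float | None]) -> dict[str, int | None]:
    """Nearest-integer-percent presentation of a metrics dict."""
    return {k: (None if v is None else int(round(v))) for k, v in m.items()}


# -- k-fold partitioning -----------------------------------------------------

def kfold_partition(patchset: PatchSet, k: int = 5, seed: int = 0,
                    level: str = "patch") -> list[np.ndarray]:
    """Shuffle and split into k near-equal folds of patch indices.

    level='patch' shuffles and partitions individual patches (the reference
    protocol); level='subject' partitions subjects, keeping all of a
    subject's patches inside one fold (no subject straddles train and
    validation).
    """
    rng = np.random.default_rng(seed)
    n = len(patchset)
    if level == "patch":
        if k > n:
            raise ValueError(f"k={k} exceeds {n} patches")
        perm = rng.permutation(n)
        return [np.sort(fold) for fold in np.array_split(perm, k)]
    if level == "subject":
        subjects = np.unique(patchset.subject_ids)
        if k > len(subjects):
            raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
        perm = rng.permutation(len(subjects))
        sid = patchset.subject_ids
        folds = []
        for chunk in np.array_split(perm, k):
            members = set(subjects[chunk])
            folds.append(np.flatnonzero([s in members for s in sid]))
        return folds
    raise ValueError(f"unknown CV level {level!r}")


@dataclass
class CvResult:
    """Per-fold and mean metrics plus pooled validation scores for ROC use."""

    fold_metrics: list[dict]
    mean_metrics: dict[str, float | None]
    pooled_scores: np.ndarray        # P(glioblastoma) per validation patch
    pooled_labels: np.ndarray        # true labels, pooled over folds
    k: int
    level: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i + 1, **m) for i, m in enumerate(self.fold_metrics)]
        rows.append(dict(fold="mean", **self.mean_metrics))
        return pd.DataFrame(rows)


def cross_validate(patchset: PatchSet, make_classifier, k: int = 5,
                   seed: int = 0, level: str = "patch") -> CvResult:
    """k-fold cross-validation of any fit/predict_proba classifier.

    ``make_classifier(fold_index)`` must return an unfitted object with
    ``fit(PatchSet)`` and ``predict_proba(PatchSet) -> (n, 2)``. Each fold is
    held out once while the others train; reported values are across-fold
    means. A fold whose training or validation side lacks a class is skipped
    with a warning.
    """
    folds = kfold_partition(patchset, k=k, seed=seed, level=level)
    all_idx = np.arange(len(patchset))
    fold_metrics: list[dict] = []
    scores, labels = [], []
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        train_set = _subset(patchset, train_idx)
        val_set = _subset(patchset, val_idx)
        if len(set(train_set.labels)) < 2 or len(set(val_set.labels)) < 2:
            logger.warning("fold %d skipped: a class is missing", i + 1)
            continue
        clf = make_classifier(i)
        clf.fit(train_set)
        probs = np.asarray(clf.predict_proba(val_set))
        pred = np.array([CLASSES[j] for j in probs.argmax(axis=1)])
        m = classification_metrics(confusion_counts(pred, val_set.labels))
        fold_metrics.append(m)
        scores.append(probs[:, 0])
        labels.append(val_set.labels)
    if not fold_metrics:
        raise ValueError("no usable folds")
    mean = {key: float(np.mean([m[key] for m in fold_metrics
                                if m[key] is not None]))
            for key in fold_metrics[0]}
    return CvResult(fold_metrics=fold_metrics, mean_metrics=mean,
                    pooled_scores=np.concatenate(scores),
                    pooled_labels=np.concatenate(labels),
                    k=k, level=level, seed=seed)


def _subset(patchset: PatchSet, idx: np.ndarray) -> PatchSet:
    return PatchSet([patchset.patches[i] for i in idx], patchset.map_kind,
                    patchset.provenance)


# -- ROC / AUC / DeLong ------------------------------------------------------

@dataclass
class RocCurve:
    """ROC points (FPR, TPR, thresholds) and the Mann-Whitney AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def _positive_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "SUO":
        return labels == POSITIVE
    return labels.astype(bool)


def mann_whitney_auc(scores, labels) -> float:
    """P(random positive outscores a random negative), ties counted 1/2."""
    pos = _positive_mask(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes")
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def roc_and_auc(scores, labels) -> RocCurve:
    """ROC over all score thresholds; AUC via the Mann-Whitney statistic."""
    pos = _positive_mask(labels)
    s = np.asarray(scores, dtype=float)
    if pos.all() or not pos.any():
        raise ValueError("ROC needs both classes")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(pos_sorted)[distinct]
    fps = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tps / pos.sum()]
    fpr = np.r_[0.0, fps / (~pos).sum()]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds,
                    auc=mann_whitney_auc(s, pos), scores=s,
                    labels=np.asarray(labels))


def _placements(scores_pos: np.ndarray, scores_neg: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) for one score vector."""
    cmp = (scores_pos[:, None] > scores_neg[None, :]).astype(float)
    cmp += 0.5 * (scores_pos[:, None] == scores_neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)   # V10 (per pos), V01 (per neg)


def delong_compare(scores_a, scores_b, labels) -> dict[str, float]:
    """DeLong test for two correlated AUCs measured on the same units.

    Returns AUC_A, AUC_B, the AUC difference, z, and the two-sided p-value
    from the structural-components covariance estimate. Identical
    classifiers (zero-variance difference, equal AUCs) give p = 1; a
    zero-variance difference with unequal AUCs is an error.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    pos = _positive_mask(labels)
    if sa.shape != sb.shape or sa.shape[0] != pos.shape[0]:
        raise ValueError("scores must be paired on identical units")
    if pos.all() or not pos.any():
        raise ValueError("DeLong needs both classes")
    m, n = int(pos.sum()), int((~pos).sum())
    v10_a, v01_a = _placements(sa[pos], sa[~pos])
    v10_b, v01_b = _placements(sb[pos], sb[~pos])
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    V10 = np.vstack([v10_a, v10_b])
    V01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(V10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(V01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        if abs(diff) < 1e-12:
            return {"auc_a": auc_a, "auc_b": auc_b, "diff": 0.0,
                    "z": 0.0, "p": 1.0}
        raise ValueError("zero variance of the AUC difference with "
                         "differing AUCs; DeLong test undefined")
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff,
            "z": float(z), "p": float(p)}
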