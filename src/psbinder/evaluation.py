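"""Cross-validated evaluation: stratified fivefold CV, the confusion-matrix
metric suite (sensitivity, specificity, accuracy, Matthews correlation
coefficient), and ROC/AUC.

Headline Sn/Sp/Acc/MCC are fold averages; the pooled confusion matrix and
pooled-accuracy are also retained (at n ~ 200 the two differ by well under
one percentage point). AUC is computed on the pooled held-out scores because
a five-point average ROC is ill-defined at this sample size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .svm import SVMConfig


def kfold_split(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> List[np.ndarray]:
    """Stratified k-fold test-index groups, deterministic given seed.

    Group sizes differ by at most one per class; the union of groups covers
    every index exactly once.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), labels)]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positives are binders (PSBPs)."""

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

    @staticmethod
    def from_predictions(
        y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        return ConfusionMatrix(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    """Sn/Sp/Acc as fractions, MCC in [-1, 1].

    ``mcc_undefined`` flags the degenerate case where a factor of the MCC
    denominator is zero; by convention MCC is then reported as 0.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_undefined: bool = False


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    """Exact confusion-matrix arithmetic.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / cm.total
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return Metrics(sn=sn, sp=sp, acc=acc, mcc=0.0, mcc_undefined=True)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def mann_whitney_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> float:
    """AUC as the Mann-Whitney concordance statistic: the fraction of
    (positive, negative) pairs where the positive scores higher, ties
    counted one half. Exhaustive pair enumeration — O(n+ * n-)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[float, np.ndarray]:
    """ROC by threshold sweep and AUC by the trapezoidal rule.

    The trapezoid value is cross-checked at run time against the
    Mann-Whitney pair-counting statistic (the two are equal identities);
    returns (auc, roc_points) with roc_points an (m, 2) array of
    (false positive rate, true positive rate).
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("AUC requires both classes")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    mw = mann_whitney_auc(scores, labels)
    if abs(auc - mw) > 1e-9:
        raise AssertionError(
            f"trapezoidal AUC {auc!r} disagrees with Mann-Whitney {mw!r}"
        )
    return auc, np.column_stack([fpr, tpr])


@dataclass
class MetricsReport:
    """Full CV evaluation: fold-averaged headline metrics, per-fold
    breakdown, pooled confusion matrix, and pooled-score AUC."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    folds: List[Metrics]
    confusion: ConfusionMatrix
    roc_points: Optional[np.ndarray] = None
    seed: Optional[int] = None

    @property
    def pooled(self) -> Metrics:
        return metrics_from_confusion(self.confusion)

    def to_dict(self) -> Dict:
        return {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "pooled_acc": self.pooled.acc,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "folds": [
                {"sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc}
                for m in self.folds
            ],
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def roc_tsv(self) -> str:
        if self.roc_points is None:
            raise ValueError("no ROC points recorded")
        lines = ["fpr\ttpr"]
        lines += [f"{a:.6f}\t{b:.6f}" for a, b in self.roc_points]
        return "\n".join(lines) + "\n"


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    config: SVMConfig,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV of an RBF-SVM with the given hyperparameters.

    Each fold trains on the other k-1 groups and scores the held-out group.
    Class calls use the SVM decision rule and the ROC scores are the raw
    decision values: both are monotone in the fitted margin, which keeps
    the evaluation independent of probability-calibration quirks (the
    calibrated model is what :func:`psbinder.svm.predict` serves to users).
    Sn/Sp/Acc/MCC are averaged over folds; ROC/AUC uses the pooled
    held-out scores.
    """
    from sklearn.svm import SVC

    y = np.asarray(y)
    folds = kfold_split(y, k=k, seed=seed)
    n = y.size
    per_fold: List[Metrics] = []
    pooled_scores = np.zeros(n)
    pooled_pred = np.zeros(n, dtype=int)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        clf = SVC(C=config.c, gamma=config.g, kernel="rbf")
        clf.fit(X[train_mask], y[train_mask])
        preds = clf.predict(X[test_idx]).astype(int)
        # binary SVC orients decision_function toward classes_[1] == 1
        pooled_scores[test_idx] = clf.decision_function(X[test_idx])
        pooled_pred[test_idx] = preds
        per_fold.append(
            metrics_from_confusion(
                ConfusionMatrix.from_predictions(y[test_idx], preds)
            )
        )
    auc, roc_points = roc_auc(pooled_scores, y)
    pooled_cm = ConfusionMatrix.from_predictions(y, pooled_pred)
    return MetricsReport(
        sn=float(np.mean([m.sn for m in per_fold])),
        sp=float(np.mean([m.sp for m in per_fold])),
        acc=float(np.mean([m.acc for m in per_fold])),
        mcc=float(np.mean([m.mcc for m in per_fold])),
        auc=auc,
        folds=per_fold,
        confusion=pooled_cm,
        roc_points=roc_points,
        seed=seed,
    )
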