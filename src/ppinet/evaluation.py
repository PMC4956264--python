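"""Evaluation: confusion-matrix metrics, ROC/PR curves, node-wise CV.

Pair-level scores are evaluated with ROC and precision-recall curves (ties
grouped, one operating point per distinct score; AUROC by trapezoid, AUPR
by step-wise interpolation). Cross-validation splits *nodes*, not pairs:
each fold evaluates only test x test pairs, train x test pairs are excluded
from both training and evaluation, which avoids the optimism of pair-wise
splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .kernels import InteractionNetwork

__all__ = [
    "ConfusionMatrix",
    "Curve",
    "CVFolds",
    "confusion_at_threshold",
    "roc_curve",
    "pr_curve",
    "auroc",
    "aupr",
    "node_cv_split",
    "fold_eval_pairs",
]


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.FP + self.TN

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def _rate(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def tpr(self) -> float:  # sensitivity / recall
        return self._rate(self.TP, self.P)

    @property
    def tnr(self) -> float:  # specificity
        return self._rate(self.TN, self.N)

    @property
    def fpr(self) -> float:
        return self._rate(self.FP, self.N)

    @property
    def fnr(self) -> float:
        return self._rate(self.FN, self.P)

    @property
    def precision(self) -> float:
        return self._rate(self.TP, self.TP + self.FP)

    @property
    def accuracy(self) -> float:
        return self._rate(self.TP + self.TN, self.total)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    labels = np.where(labels > 0, 1, 0).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores, labels


def confusion_at_threshold(scores, labels, theta: float) -> ConfusionMatrix:
    """Counts with predicted positive iff score > theta (strict)."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores > theta
    return ConfusionMatrix(
        TP=int(np.sum(pred & (labels == 1))),
        FP=int(np.sum(pred & (labels == 0))),
        FN=int(np.sum(~pred & (labels == 1))),
        TN=int(np.sum(~pred & (labels == 0))),
    )


@dataclass
class Curve:
    """Ordered operating points with an area statistic."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: float
    kind: str  # "ROC" or "PR"

    def precision_at_recall(self, recall: float) -> float:
        """Best precision achievable at recall >= the given level (PR only)."""
        if self.kind != "PR":
            raise ValueError("precision_at_recall applies to PR curves")
        mask = self.x >= recall
        if not mask.any():
            return float("nan")
        return float(self.y[mask].max())


def roc_curve(scores, labels) -> Curve:
    """ROC curve (FPR, TPR) with trapezoidal AUROC; ties grouped."""
    scores, labels = _check_scores_labels(scores, labels)
    P = int(labels.sum())
    N = len(labels) - P
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    cuts = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(l)[cuts]
    fp = np.cumsum(1 - l)[cuts]
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    thresholds = np.r_[np.inf, s[cuts]]
    area = float(np.trapezoid(tpr, fpr))
    return Curve(x=fpr, y=tpr, thresholds=thresholds, area=area, kind="ROC")


def pr_curve(scores, labels) -> Curve:
    """PR curve from pseudo-point (0, 1) to (1, P/(P+N)); step-wise AUPR.

    The area equals average precision (no linear interpolation between
    operating points).
    """
    scores, labels = _check_scores_labels(scores, labels)
    P = int(labels.sum())
    if P == 0:
        raise ValueError("PR requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    cuts = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(l)[cuts]
    pp = cuts + 1.0
    recall = np.r_[0.0, tp / P]
    precision = np.r_[1.0, tp / pp]
    thresholds = np.r_[np.inf, s[cuts]]
    # step-wise area: sum precision * recall increment
    area = float(np.sum(np.diff(recall) * precision[1:]))
    return Curve(x=recall, y=precision, thresholds=thresholds, area=area, kind="PR")


def auroc(scores, labels) -> float:
    scores, labels = _check_scores_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    scores, labels = _check_scores_labels(scores, labels)
    return float(average_precision_score(labels, scores))


@dataclass
class CVFolds:
    k: int
    folds: list[np.ndarray]
    seed: int | None

    def __post_init__(self) -> None:
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most one")
        all_idx = np.sort(np.concatenate(self.folds))
        if not np.array_equal(all_idx, np.arange(len(all_idx))):
            raise ValueError("folds must partition the node set")


def node_cv_split(ids, k: int, seed: int | None = 0) -> CVFolds:
    """Random balanced partition of the nodes into k folds."""
    m = len(ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > m:
        raise ValueError("more folds than nodes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    return CVFolds(k=k, folds=folds, seed=seed)


def fold_eval_pairs(
    folds: CVFolds, net: InteractionNetwork, fold_index: int
) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Training nodes, evaluated test x test pairs and their 0/1 labels.

    Only pairs with both endpoints in the held-out fold are evaluated;
    train x test pairs belong to neither training nor evaluation.
    """
    if not 0 <= fold_index < folds.k:
        raise ValueError("fold index out of range")
    test = folds.folds[fold_index]
    test_set = set(test.tolist())
    train = np.array(
        sorted(set(range(net.n_proteins)) - test_set), dtype=int
    )
    pairs = [
        (int(test[i]), int(test[j]))
        for i in range(len(test))
        for j in range(i + 1, len(test))
    ]
    labels = np.array([net.adjacency[i, j] for i, j in pairs], dtype=int)
    return train, pairs, labels
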