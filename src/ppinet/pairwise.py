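"""Link prediction as binary classification on protein pairs.

Pairs of proteins become training patterns: a base kernel on proteins is
lifted to a kernel on unordered pairs (direct product, tensor product or
metric-learning variants) and a soft-margin kernel SVM is trained on the
precomputed pair-pair Gram matrix.

The full pair-pair Gram matrix over all pairs of an m-protein network is
O(m^4) in memory; :func:`pair_kernel` therefore evaluates lazy blocks for
explicitly given pair lists only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .kernels import InteractionNetwork, KernelMatrix

__all__ = [
    "PairDataset",
    "PairClassifier",
    "enumerate_pairs",
    "pair_kernel",
    "train_pair_classifier",
    "score_pairs",
    "PAIR_KERNEL_VARIANTS",
]

PAIR_KERNEL_VARIANTS = ("DRCT", "TPPK", "MLPK")


@dataclass
class PairDataset:
    """Labeled unordered protein pairs with labels in {-1, +1}."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must have equal length")
        if not set(np.unique(self.labels)).issubset({-1, 1}):
            raise ValueError("labels must be -1/+1")
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())


def enumerate_pairs(
    net: InteractionNetwork,
    mode: str = "all",
    *,
    negative_ratio: float = 5.0,
    seed: int | None = 0,
) -> PairDataset:
    """All unordered pairs of the network labeled +1 (edge) / -1 (non-edge).

    ``mode='balanced-subsample'`` keeps every positive and subsamples
    negatives to ``negative_ratio`` negatives per positive (seeded).
    """
    m = net.n_proteins
    if m < 2:
        raise ValueError("need at least two proteins to enumerate pairs")
    if mode not in ("all", "balanced-subsample"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = net.protein_ids
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    for i in range(m):
        for j in range(i + 1, m):
            pairs.append((ids[i], ids[j]))
            labels.append(1 if net.adjacency[i, j] else -1)
    labels_arr = np.array(labels)
    if mode == "balanced-subsample":
        rng = np.random.default_rng(seed)
        pos = np.nonzero(labels_arr == 1)[0]
        neg = np.nonzero(labels_arr == -1)[0]
        n_neg = min(len(neg), int(round(negative_ratio * len(pos))))
        keep = np.sort(np.concatenate([pos, rng.choice(neg, n_neg, replace=False)]))
        pairs = [pairs[i] for i in keep]
        labels_arr = labels_arr[keep]
    return PairDataset(pairs, labels_arr)


def pair_kernel(
    K_X: KernelMatrix,
    left: list[tuple[str, str]],
    right: list[tuple[str, str]],
    variant: str = "TPPK",
) -> np.ndarray:
    """Pair-pair kernel block between two lists of unordered pairs.

    For pairs (a, b) and (c, d) with base kernel k:

    - DRCT: k(a,c) k(b,d)
    - TPPK: k(a,c) k(b,d) + k(a,d) k(b,c)
    - MLPK: (k(a,c) - k(a,d) - k(b,c) + k(b,d))^2
    """
    if variant not in PAIR_KERNEL_VARIANTS:
        raise ValueError(f"unknown pair-kernel variant {variant!r}")
    index = {pid: i for i, pid in enumerate(K_X.entity_ids)}
    try:
        la = np.array([index[p[0]] for p in left])
        lb = np.array([index[p[1]] for p in left])
        rc = np.array([index[p[0]] for p in right])
        rd = np.array([index[p[1]] for p in right])
    except KeyError as exc:
        raise KeyError(f"pair member {exc} not indexed in the base kernel") from exc
    K = K_X.values
    k_ac = K[np.ix_(la, rc)]
    k_ad = K[np.ix_(la, rd)]
    k_bc = K[np.ix_(lb, rc)]
    k_bd = K[np.ix_(lb, rd)]
    if variant == "DRCT":
        return k_ac * k_bd
    if variant == "TPPK":
        return k_ac * k_bd + k_ad * k_bc
    return (k_ac - k_ad - k_bc + k_bd) ** 2


@dataclass
class PairClassifier:
    """Soft-margin kernel SVM over a precomputed pair kernel."""

    svc: SVC = field(repr=False)
    train_pairs: list[tuple[str, str]]
    C: float
    variant: str

    def decision_values(self, K_cross: np.ndarray) -> np.ndarray:
        K_cross = np.asarray(K_cross, dtype=float)
        if K_cross.ndim != 2 or K_cross.shape[1] != len(self.train_pairs):
            raise ValueError(
                "cross-kernel columns must align with the training pairs"
            )
        return self.svc.decision_function(K_cross)


def train_pair_classifier(
    K_pair: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    *,
    class_weighting: bool = True,
    train_pairs: list[tuple[str, str]] | None = None,
    variant: str = "TPPK",
) -> PairClassifier:
    """Fit the SVM on a precomputed pair-pair Gram matrix.

    ``class_weighting`` re-weights C inversely to class frequency (on by
    default, since non-interacting pairs vastly outnumber interacting ones).
    """
    K_pair = np.asarray(K_pair, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(K_pair).all():
        raise ValueError("pair kernel contains non-finite values")
    if K_pair.shape[0] != K_pair.shape[1] or K_pair.shape[0] != len(labels):
        raise ValueError("kernel/label dimensions mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    svc = SVC(
        C=C,
        kernel="precomputed",
        class_weight="balanced" if class_weighting else None,
    )
    svc.fit(K_pair, labels)
    if train_pairs is None:
        train_pairs = [(str(i), str(i) + "'") for i in range(len(labels))]
    return PairClassifier(svc=svc, train_pairs=list(train_pairs), C=C, variant=variant)


def score_pairs(model: PairClassifier, K_cross: np.ndarray) -> np.ndarray:
    """Decision values for test pairs given their kernel against training pairs."""
    return model.decision_values(K_cross)
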