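"""Output kernel trees.

CART-style top-down induction where splits maximize variance reduction of
the *output-kernel* feature map, evaluated entirely through the kernel
trick; a bagged ensemble with per-node random feature subsets serves as the
forest variant. Pair scores are approximated from leaf co-membership: the
predicted output-kernel value for two inputs is the mean of the training
output-kernel block between their two leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernels import FeatureTable, KernelMatrix

__all__ = [
    "SplitTest",
    "OK3Node",
    "OK3Tree",
    "OK3Ensemble",
    "TreeConfig",
    "output_variance",
    "split_score",
    "grow_tree",
    "fit_ensemble",
    "ok3_pair_score",
    "predict_kernel",
]


def output_variance(subset: Sequence[int], K_Y: KernelMatrix | np.ndarray) -> float:
    """Kernel-trick variance of the output feature vectors over ``subset``.

    var = (1/N) sum_i k(i,i) - (1/N^2) sum_ij k(i,j); nonnegative for PSD K.
    """
    idx = np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("empty subset")
    K = K_Y.values if isinstance(K_Y, KernelMatrix) else np.asarray(K_Y)
    block = K[np.ix_(idx, idx)]
    n = idx.size
    return float(np.trace(block) / n - block.sum() / n**2)


def split_score(
    S: Sequence[int],
    S_l: Sequence[int],
    S_r: Sequence[int],
    K_Y: KernelMatrix | np.ndarray,
) -> float:
    """Variance reduction of splitting S into (S_l, S_r); nonnegative."""
    S, S_l, S_r = set(S), set(S_l), set(S_r)
    if not S_l or not S_r or (S_l | S_r) != S or (S_l & S_r):
        raise ValueError("S_l and S_r must be a nonempty partition of S")
    n, nl, nr = len(S), len(S_l), len(S_r)
    return (
        output_variance(sorted(S), K_Y)
        - nl / n * output_variance(sorted(S_l), K_Y)
        - nr / n * output_variance(sorted(S_r), K_Y)
    )


@dataclass(frozen=True)
class SplitTest:
    """Threshold test on one feature: route left iff value <= threshold."""

    feature: int
    threshold: float

    def goes_left(self, x: np.ndarray) -> bool:
        return bool(x[self.feature] <= self.threshold)


@dataclass
class OK3Node:
    test: SplitTest | None = None
    left: "OK3Node | None" = None
    right: "OK3Node | None" = None
    members: np.ndarray | None = None  # leaf only: training indices

    @property
    def is_leaf(self) -> bool:
        return self.test is None


@dataclass
class TreeConfig:
    max_depth: int | None = None
    min_samples: int = 2
    var_tol: float = 1e-12
    max_features: int | None = None  # per-node random feature subset; None = all


@dataclass
class OK3Tree:
    root: OK3Node
    n_features: int
    feature_importance: np.ndarray = field(repr=False)

    def leaf_for(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature vector")
        if x.shape != (self.n_features,):
            raise ValueError("feature dimension mismatch")
        node = self.root
        while not node.is_leaf:
            node = node.left if node.test.goes_left(x) else node.right
        return node.members

    def leaves(self) -> list[OK3Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def to_dict(self) -> dict:
        def rec(node: OK3Node) -> dict:
            if node.is_leaf:
                return {"members": node.members.tolist()}
            return {
                "feature": node.test.feature,
                "threshold": node.test.threshold,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return {"n_features": self.n_features, "root": rec(self.root)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "OK3Tree":
        def rec(nd: dict) -> OK3Node:
            if "members" in nd:
                return OK3Node(members=np.asarray(nd["members"], dtype=int))
            return OK3Node(
                test=SplitTest(nd["feature"], nd["threshold"]),
                left=rec(nd["left"]),
                right=rec(nd["right"]),
            )

        return cls(
            root=rec(d["root"]),
            n_features=d["n_features"],
            feature_importance=np.zeros(d["n_features"]),
        )


def _best_split(
    X: np.ndarray,
    idx: np.ndarray,
    K: np.ndarray,
    candidates: np.ndarray,
) -> tuple[float, SplitTest | None, np.ndarray | None, np.ndarray | None]:
    """Exhaustive search over midpoint thresholds of the candidate features.

    Incremental kernel sums make one feature scan O(N^2). Ties in score are
    broken by lowest feature index, then lowest threshold.
    """
    n = idx.size
    block = K[np.ix_(idx, idx)]
    diag = np.diag(block)
    parent_var = diag.mean() - block.sum() / n**2
    best = (-np.inf, None, None, None)
    for f in candidates:
        vals = X[idx, f]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        # running sums for the left child as points move across
        sum_diag_l = 0.0
        sum_block_l = 0.0
        cross = np.zeros(n)  # cross[j] = sum over left members of block[perm] col j
        bp = block[np.ix_(order, order)]
        dp = diag[order]
        total_diag = diag.sum()
        total_block = block.sum()
        for t in range(n - 1):
            sum_diag_l += dp[t]
            sum_block_l += 2.0 * cross[t] + bp[t, t]
            cross += bp[t]
            if sv[t] == sv[t + 1]:
                continue
            nl, nr = t + 1, n - t - 1
            sum_diag_r = total_diag - sum_diag_l
            # sum of the right block = total - left - 2*cross(left, right)
            cross_lr = cross[t + 1 :].sum()
            sum_block_r = total_block - sum_block_l - 2.0 * cross_lr
            var_l = sum_diag_l / nl - sum_block_l / nl**2
            var_r = sum_diag_r / nr - sum_block_r / nr**2
            score = parent_var - nl / n * var_l - nr / n * var_r
            thr = 0.5 * (sv[t] + sv[t + 1])
            key = (score, -f, -thr)
            if key > (best[0], -(best[1].feature if best[1] else np.inf),
                      -(best[1].threshold if best[1] else np.inf)):
                left_idx = idx[order[: t + 1]]
                right_idx = idx[order[t + 1 :]]
                best = (score, SplitTest(int(f), float(thr)), left_idx, right_idx)
    return best


def grow_tree(
    features: FeatureTable,
    K_Y: KernelMatrix,
    config: TreeConfig | None = None,
    rng: np.random.Generator | None = None,
    sample_indices: np.ndarray | None = None,
) -> OK3Tree:
    """Grow a single output-kernel tree by recursive variance-reduction splits."""
    if features.protein_ids != K_Y.entity_ids:
        raise ValueError("features and output kernel must index the same proteins")
    config = config or TreeConfig()
    rng = rng or np.random.default_rng()
    X = features.values
    K = K_Y.values
    q = X.shape[1]
    importance = np.zeros(q)
    root_idx = (
        np.arange(X.shape[0]) if sample_indices is None
        else np.asarray(sample_indices, dtype=int)
    )

    def build(idx: np.ndarray, depth: int) -> OK3Node:
        if (
            idx.size < config.min_samples
            or (config.max_depth is not None and depth >= config.max_depth)
            or output_variance(idx, K) <= config.var_tol
        ):
            return OK3Node(members=idx)
        if config.max_features is None or config.max_features >= q:
            candidates = np.arange(q)
        else:
            candidates = np.sort(rng.choice(q, size=config.max_features, replace=False))
        score, test, li, ri = _best_split(X, idx, K, candidates)
        if test is None or score <= config.var_tol:
            return OK3Node(members=idx)
        importance[test.feature] += score
        return OK3Node(test=test, left=build(li, depth + 1), right=build(ri, depth + 1))

    root = build(root_idx, 0)
    return OK3Tree(root=root, n_features=q, feature_importance=importance)


@dataclass
class OK3Ensemble:
    trees: list[OK3Tree]
    bootstrap_indices: list[np.ndarray]
    n_features: int

    @property
    def feature_importance(self) -> np.ndarray:
        return np.mean([t.feature_importance for t in self.trees], axis=0)


def fit_ensemble(
    features: FeatureTable,
    K_Y: KernelMatrix,
    n_trees: int = 100,
    *,
    bootstrap: bool = True,
    max_features: int | None = "sqrt",  # type: ignore[assignment]
    config: TreeConfig | None = None,
    seed: int | None = None,
) -> OK3Ensemble:
    """Random forest of output-kernel trees (bootstrap + random feature subsets)."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    m, q = features.values.shape
    if max_features == "sqrt":
        max_features = int(np.ceil(np.sqrt(q)))
    cfg = config or TreeConfig()
    cfg = TreeConfig(cfg.max_depth, cfg.min_samples, cfg.var_tol, max_features)
    trees, boots = [], []
    for _ in range(n_trees):
        if bootstrap:
            idx = np.unique(rng.choice(m, size=m, replace=True))
        else:
            idx = np.arange(m)
        trees.append(grow_tree(features, K_Y, cfg, rng, sample_indices=idx))
        boots.append(idx)
    return OK3Ensemble(trees=trees, bootstrap_indices=boots, n_features=q)


def _leaf_pair_mean(members1: np.ndarray, members2: np.ndarray, K: np.ndarray) -> float:
    return float(K[np.ix_(members1, members2)].mean())


def ok3_pair_score(
    model: OK3Tree | OK3Ensemble,
    x_u: np.ndarray,
    x_v: np.ndarray,
    K_Y_train: KernelMatrix | np.ndarray,
) -> float:
    """Predicted output-kernel value for the input pair (x_u, x_v)."""
    K = K_Y_train.values if isinstance(K_Y_train, KernelMatrix) else np.asarray(K_Y_train)
    trees = model.trees if isinstance(model, OK3Ensemble) else [model]
    vals = [
        _leaf_pair_mean(t.leaf_for(np.asarray(x_u)), t.leaf_for(np.asarray(x_v)), K)
        for t in trees
    ]
    return float(np.mean(vals))


def predict_kernel(
    model: OK3Tree | OK3Ensemble,
    X_test: np.ndarray,
    K_Y_train: KernelMatrix | np.ndarray,
) -> np.ndarray:
    """Full predicted output-kernel block over the test rows (test x test)."""
    K = K_Y_train.values if isinstance(K_Y_train, KernelMatrix) else np.asarray(K_Y_train)
    X_test = np.asarray(X_test, dtype=float)
    n = X_test.shape[0]
    trees = model.trees if isinstance(model, OK3Ensemble) else [model]
    out = np.zeros((n, n))
    for tree in trees:
        leaves = tree.leaves()
        leaf_of = {}
        assign = np.empty(n, dtype=int)
        for li, leaf in enumerate(leaves):
            leaf_of[id(leaf)] = li
        for i in range(n):
            node = tree.root
            while not node.is_leaf:
                node = node.left if node.test.goes_left(X_test[i]) else node.right
            assign[i] = leaf_of[id(node)]
        nl = len(leaves)
        means = np.zeros((nl, nl))
        for a in range(nl):
            for b in range(a, nl):
                means[a, b] = means[b, a] = _leaf_pair_mean(
                    leaves[a].members, leaves[b].members, K
                )
        out += means[np.ix_(assign, assign)]
    return out / len(trees)
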