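"""End-to-end transfer-learning workflow.

Trains a learner (IOKR supervised/semi-supervised, OK3 ensemble or pairwise
SVM) on a source species' features and interaction network, optionally
after learning input-kernel mixture weights with MKL, and scores all
protein pairs of a target species whose features live in the same space.
Also provides the node-wise cross-validated transfer evaluation used by the
synthetic benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, iokr, mkl, ok3, pairwise
from .kernels import (
    FeatureTable,
    InteractionNetwork,
    KernelMatrix,
    center_kernel,
    diffusion_kernel,
)

logger = logging.getLogger("ppinet")

LEARNERS = ("iokr", "iokr-semi", "ok3", "pairwise-svm")
MKL_METHODS = ("unimkl", "align", "alignf", "pnorm")

__all__ = ["TransferConfig", "TransferResult", "run_transfer", "transfer_node_cv",
           "LEARNERS", "MKL_METHODS"]


@dataclass
class TransferConfig:
    """Configuration of the transfer workflow.

    The default recipe is semi-supervised IOKR with p-norm path MKL.
    """

    learner: str = "iokr-semi"
    mkl_method: str = "pnorm"
    beta: float = 1.0               # output diffusion kernel
    lambda1: float = 0.1            # IOKR ridge weight
    lambda2: float = 0.01           # IOKR smoothness weight
    iokr_beta: float = 1.0          # smoothness operator diffusion
    svm_C: float = 1.0
    pair_variant: str = "TPPK"
    negative_ratio: float = 5.0
    n_trees: int = 100
    cv_folds: int = 5
    seed: int = 0
    threshold: float | None = None  # None: report ranked scores only
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.mkl_method not in MKL_METHODS:
            raise ValueError(f"unknown MKL method {self.mkl_method!r}")


@dataclass
class TransferResult:
    target_ids: list[str]
    scores: np.ndarray                  # symmetric target x target score block
    ranked_pairs: list[tuple[str, str, float]]
    predicted: InteractionNetwork | None
    weights: mkl.MKLWeights | None
    config: TransferConfig


def _mkl_weights(
    method: str, bank: mkl.KernelBank, K_Y: np.ndarray, cfg: TransferConfig
) -> mkl.MKLWeights:
    if method == "unimkl":
        return mkl.uniform_weights(bank)
    if method == "align":
        return mkl.align_weights(bank, K_Y)
    if method == "alignf":
        return mkl.alignf_weights(bank, K_Y)
    return mkl.pnorm_path_weights(
        bank, K_Y,
        lambda1=cfg.extras.get("pnorm_lambda1", 1.0),
        lambda2=cfg.extras.get("pnorm_lambda2", 1.0),
        sparsity_target=cfg.extras.get("sparsity_target"),
    )


def _score_block(
    cfg: TransferConfig,
    K_joint: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    net_train: InteractionNetwork,
    features_train: FeatureTable | None,
    X_test: np.ndarray | None,
) -> np.ndarray:
    """Symmetric test x test pair-score block for the configured learner."""
    K_Y = diffusion_kernel(net_train, cfg.beta)
    K_tr = K_joint[np.ix_(train_idx, train_idx)]
    K_te_tr = K_joint[np.ix_(test_idx, train_idx)]
    if cfg.learner == "iokr":
        model = iokr.fit_iokr_supervised(K_tr, K_Y.values, cfg.lambda1)
        return iokr.predict_kernel_block(model, K_te_tr)
    if cfg.learner == "iokr-semi":
        order = np.concatenate([train_idx, test_idx])
        K_Xn = K_joint[np.ix_(order, order)]
        model = iokr.fit_iokr_semisupervised(
            K_Xn, K_Y.values, cfg.lambda1, cfg.lambda2, cfg.iokr_beta
        )
        cols = K_joint[np.ix_(test_idx, order)]
        return iokr.predict_kernel_block(model, cols)
    if cfg.learner == "ok3":
        if features_train is None or X_test is None:
            raise ValueError("OK3 requires explicit feature tables")
        model = ok3.fit_ensemble(
            features_train, K_Y, n_trees=cfg.n_trees, seed=cfg.seed
        )
        return ok3.predict_kernel(model, X_test, K_Y.values)
    # pairwise SVM
    ds = pairwise.enumerate_pairs(
        net_train, "balanced-subsample",
        negative_ratio=cfg.negative_ratio, seed=cfg.seed,
    )
    ids_joint = [str(i) for i in range(K_joint.shape[0])]
    KX = KernelMatrix(ids_joint, K_joint, check_psd=False)
    tr_pairs = [(str(train_idx[net_train.protein_ids.index(a)]),
                 str(train_idx[net_train.protein_ids.index(b)])) for a, b in ds.pairs]
    K_pair = pairwise.pair_kernel(KX, tr_pairs, tr_pairs, cfg.pair_variant)
    model = pairwise.train_pair_classifier(
        K_pair, ds.labels, cfg.svm_C, train_pairs=tr_pairs, variant=cfg.pair_variant
    )
    te_pairs = [
        (str(test_idx[i]), str(test_idx[j]))
        for i in range(len(test_idx)) for j in range(i + 1, len(test_idx))
    ]
    block = np.zeros((len(test_idx), len(test_idx)))
    if te_pairs:
        K_cross = pairwise.pair_kernel(KX, te_pairs, tr_pairs, cfg.pair_variant)
        vals = pairwise.score_pairs(model, K_cross)
        k = 0
        for i in range(len(test_idx)):
            for j in range(i + 1, len(test_idx)):
                block[i, j] = block[j, i] = vals[k]
                k += 1
    return block


def _stacked_grams(
    banks_src: list[FeatureTable], banks_tgt: list[FeatureTable]
) -> np.ndarray:
    """One linear Gram matrix per feature table over the [source; target] rows."""
    mats = []
    for fs, ft in zip(banks_src, banks_tgt):
        if fs.n_features != ft.n_features:
            raise ValueError("feature schema mismatch between source and target")
        X = np.vstack([fs.values, ft.values])
        K = X @ X.T
        # Frobenius normalization of the centered kernel: puts bank kernels on
        # a common scale so mixture weights are comparable across kernels
        scale = np.linalg.norm(center_kernel(K), "fro") / K.shape[0]
        if scale > 0:
            K = K / scale
        mats.append(K)
    return np.stack(mats)


def _fold_weights(
    cfg: TransferConfig, mats: np.ndarray, train_idx: np.ndarray,
    net_train: InteractionNetwork,
) -> mkl.MKLWeights:
    """MKL weights learned on the training block only (no test leakage)."""
    ids = [f"s{i}" for i in range(len(train_idx))]
    bank = mkl.KernelBank(
        [KernelMatrix(ids, M[np.ix_(train_idx, train_idx)], check_psd=False)
         for M in mats]
    )
    K_Y = diffusion_kernel(net_train, cfg.beta)
    return _mkl_weights(cfg.mkl_method, bank, K_Y.values, cfg)


def run_transfer(
    config: TransferConfig,
    source_features: FeatureTable | list[FeatureTable],
    source_network: InteractionNetwork,
    target_features: FeatureTable | list[FeatureTable],
) -> TransferResult:
    """Fit on the source species and score all target-species pairs.

    Multiple feature tables form a kernel bank (one linear kernel each) whose
    mixture weights are learned on the source block with the configured MKL
    method; a single table skips MKL with unit weight.
    """
    src = [source_features] if isinstance(source_features, FeatureTable) else list(source_features)
    tgt = [target_features] if isinstance(target_features, FeatureTable) else list(target_features)
    if len(src) != len(tgt):
        raise ValueError("source and target must provide the same kernel bank")
    if src[0].protein_ids != source_network.protein_ids:
        if set(src[0].protein_ids) >= set(source_network.protein_ids):
            order = [src[0].protein_ids.index(p) for p in source_network.protein_ids]
            src = [s.subset(order) for s in src]
        else:
            raise ValueError("source features must cover the network's proteins")
    mats = _stacked_grams(src, tgt)
    n_src = src[0].n_proteins
    weights = _fold_weights(config, mats, np.arange(n_src), source_network)
    K_joint = np.tensordot(weights.mu, mats, axes=1)
    n_tgt = tgt[0].n_proteins
    train_idx = np.arange(n_src)
    test_idx = np.arange(n_src, n_src + n_tgt)
    X_test = np.hstack([t.values for t in tgt]) if config.learner == "ok3" else None
    feats_train = (
        FeatureTable(src[0].protein_ids, np.hstack([s.values for s in src]))
        if config.learner == "ok3" else None
    )
    block = _score_block(
        config, K_joint, train_idx, test_idx, source_network, feats_train, X_test
    )
    block = (block + block.T) / 2.0
    ids = tgt[0].protein_ids
    ranked = sorted(
        (
            (ids[i], ids[j], float(block[i, j]))
            for i in range(n_tgt) for j in range(i + 1, n_tgt)
        ),
        key=lambda t: -t[2],
    )
    predicted = None
    if config.threshold is not None:
        A = iokr.threshold_predictions(block, config.threshold)
        predicted = InteractionNetwork(list(ids), A)
    logger.info(
        "transfer: learner=%s mkl=%s, %d source / %d target proteins",
        config.learner, config.mkl_method, n_src, n_tgt,
    )
    return TransferResult(list(ids), block, ranked, predicted, weights, config)


def transfer_node_cv(
    source_features: FeatureTable | list[FeatureTable],
    net: InteractionNetwork,
    target_features: FeatureTable | list[FeatureTable] | None = None,
    *,
    config: TransferConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> dict:
    """Node-wise cross-validated pair scoring in the transfer setting.

    Source and target proteins correspond one-to-one (the target carries the
    source labels). Each fold trains on the source data of the training
    nodes and scores test x test pairs using the *target* representation of
    the held-out nodes; only those pairs are evaluated. Returns pooled and
    per-fold AUROC/AUPR.
    """
    config = config or TransferConfig(learner="iokr", mkl_method="unimkl")
    k = k or config.cv_folds
    seed = config.seed if seed is None else seed
    src = [source_features] if isinstance(source_features, FeatureTable) else list(source_features)
    if target_features is None:
        tgt = src
    else:
        tgt = [target_features] if isinstance(target_features, FeatureTable) else list(target_features)
    m = net.n_proteins
    mats = _stacked_grams(src, tgt)
    folds = evaluation.node_cv_split(net.protein_ids, k, seed)
    all_scores, all_labels = [], []
    fold_auroc, fold_aupr = [], []
    weights = None
    for fi in range(k):
        train_nodes, pairs, labels = evaluation.fold_eval_pairs(folds, net, fi)
        test_nodes = folds.folds[fi]
        net_train = net.subnetwork(train_nodes)
        weights = _fold_weights(config, mats, train_nodes, net_train)
        K_joint = np.tensordot(weights.mu, mats, axes=1)
        feats_train = (
            FeatureTable([src[0].protein_ids[i] for i in train_nodes],
                         np.hstack([s.values[train_nodes] for s in src]))
            if config.learner == "ok3" else None
        )
        X_test = (
            np.hstack([t.values[test_nodes] for t in tgt])
            if config.learner == "ok3" else None
        )
        block = _score_block(
            config, K_joint, train_nodes, test_nodes + m, net_train,
            feats_train, X_test,
        )
        pos = {int(n): i for i, n in enumerate(test_nodes)}
        scores = np.array([block[pos[i], pos[j]] for i, j in pairs])
        all_scores.append(scores)
        all_labels.append(labels)
        if 0 < labels.sum() < len(labels):
            fold_auroc.append(evaluation.auroc(scores, labels))
            fold_aupr.append(evaluation.aupr(scores, labels))
    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    return {
        "auroc": evaluation.auroc(scores, labels),
        "aupr": evaluation.aupr(scores, labels),
        "fold_auroc": fold_auroc,
        "fold_aupr": fold_aupr,
        "fold_auroc_mean": float(np.mean(fold_auroc)) if fold_auroc else float("nan"),
        "fold_auroc_sd": float(np.std(fold_auroc)) if fold_auroc else float("nan"),
        "weights": weights,
        "k": k,
        "seed": seed,
    }
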