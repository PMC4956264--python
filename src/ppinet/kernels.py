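"""Core entity types and kernel construction.

Provides the three containers used throughout the package (feature tables,
interaction networks, kernel matrices) plus the kernel primitives: linear
kernels on node features, kernel centering, diffusion kernels on graphs and
centered kernel-target alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureTable",
    "InteractionNetwork",
    "KernelMatrix",
    "linear_kernel",
    "center_kernel",
    "diffusion_kernel",
    "centered_alignment",
    "PSD_RTOL",
]

#: relative tolerance for the PSD check: smallest eigenvalue >= -PSD_RTOL * largest
PSD_RTOL = 1e-8


def _check_ids(ids: Sequence[str]) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("entity ids must be unique")
    return ids


@dataclass
class FeatureTable:
    """Per-protein numeric feature matrix, one row per protein."""

    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = _check_ids(self.protein_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape[0] != len(self.protein_ids):
            raise ValueError("row count must equal protein id count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable([self.protein_ids[i] for i in idx], self.values[idx])


@dataclass
class InteractionNetwork:
    """Undirected interaction network as a symmetric binary adjacency matrix."""

    protein_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = _check_ids(self.protein_ids)
        A = np.asarray(self.adjacency)
        m = len(self.protein_ids)
        if A.shape != (m, m):
            raise ValueError("adjacency must be square and match id count")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        vals = set(np.unique(A).tolist())
        if not vals <= {0, 1}:
            raise ValueError("adjacency entries must be 0/1")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A.astype(np.int8)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.protein_ids[i], self.protein_ids[j]) for i, j in zip(ii, jj)]

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def subnetwork(self, indices: Sequence[int]) -> "InteractionNetwork":
        idx = np.asarray(list(indices), dtype=int)
        return InteractionNetwork(
            [self.protein_ids[i] for i in idx], self.adjacency[np.ix_(idx, idx)]
        )


@dataclass
class KernelMatrix:
    """Symmetric PSD-tolerant similarity matrix over indexed entities.

    A non-PSD matrix (smallest eigenvalue below ``-PSD_RTOL`` times the
    largest) triggers a warning rather than an error, since finite-precision
    matrix functions may dip slightly negative.
    """

    entity_ids: list[str]
    values: np.ndarray
    check_psd: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.entity_ids = _check_ids(self.entity_ids)
        K = np.asarray(self.values, dtype=float)
        m = len(self.entity_ids)
        if K.shape != (m, m):
            raise ValueError("kernel matrix must be square and match id count")
        if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
            raise ValueError("kernel matrix must be symmetric")
        self.values = (K + K.T) / 2.0
        if self.check_psd and m > 0:
            ev = np.linalg.eigvalsh(self.values)
            lo, hi = ev[0], max(ev[-1], 0.0)
            if lo < -PSD_RTOL * max(hi, 1.0):
                warnings.warn(
                    f"kernel matrix is not PSD within tolerance "
                    f"(min eigenvalue {lo:.3e}, max {hi:.3e})",
                    stacklevel=2,
                )

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def subset(self, rows: Sequence[int], cols: Sequence[int] | None = None) -> np.ndarray:
        """Raw sub-block of kernel values (not a KernelMatrix)."""
        rows = np.asarray(list(rows), dtype=int)
        cols = rows if cols is None else np.asarray(list(cols), dtype=int)
        return self.values[np.ix_(rows, cols)]


def linear_kernel(features: FeatureTable) -> KernelMatrix:
    """Inner-product kernel K[i, j] = <x_i, x_j> over the feature rows."""
    if features.n_proteins == 0:
        raise ValueError("empty feature table")
    K = features.values @ features.values.T
    return KernelMatrix(list(features.protein_ids), K)


def _centering_matrix(m: int) -> np.ndarray:
    return np.eye(m) - np.ones((m, m)) / m


def center_kernel(K: KernelMatrix | np.ndarray) -> KernelMatrix | np.ndarray:
    """Double-center a kernel: K_c = (I - 11^T/m) K (I - 11^T/m).

    All row and column means of the result are zero; the operation is
    idempotent. Accepts and returns either a :class:`KernelMatrix` or a raw
    square array.
    """
    raw = isinstance(K, np.ndarray)
    M = np.asarray(K if raw else K.values, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("kernel must be square")
    m = M.shape[0]
    # expanded form avoids building the projector explicitly
    row = M.mean(axis=1, keepdims=True)
    col = M.mean(axis=0, keepdims=True)
    Kc = M - row - col + M.mean()
    Kc = (Kc + Kc.T) / 2.0
    if raw:
        return Kc
    return KernelMatrix(list(K.entity_ids), Kc, check_psd=False)


def diffusion_kernel(net: InteractionNetwork, beta: float = 1.0) -> KernelMatrix:
    """Diffusion kernel exp(-beta * L) with L = D - Y the graph Laplacian.

    Computed by symmetric eigendecomposition of L, which keeps the result
    exactly symmetric and PSD.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    Y = net.adjacency.astype(float)
    L = np.diag(Y.sum(axis=1)) - Y
    w, V = np.linalg.eigh(L)
    K = (V * np.exp(-beta * w)) @ V.T
    return KernelMatrix(list(net.protein_ids), K)


def centered_alignment(
    K: KernelMatrix | np.ndarray,
    K_Y: KernelMatrix | np.ndarray,
    *,
    center_target: bool = True,
) -> float:
    """Centered kernel-target alignment.

    rho = <K_c, K_Yc>_F / (||K_c||_F ||K_Yc||_F), where the first argument is
    always centered and the target is centered by default (``center_target``
    controls this; with ``False`` only the first argument is centered).
    """
    A = np.asarray(K.values if isinstance(K, KernelMatrix) else K, dtype=float)
    B = np.asarray(K_Y.values if isinstance(K_Y, KernelMatrix) else K_Y, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("kernels must be square with identical dimensions")
    Ac = center_kernel(A)
    Bc = center_kernel(B) if center_target else B
    na = np.linalg.norm(Ac, "fro")
    nb = np.linalg.norm(Bc, "fro")
    if na <= 0 or nb <= 0:
        raise ValueError("degenerate kernel: zero Frobenius norm after centering")
    return float(np.sum(Ac * Bc) / (na * nb))
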