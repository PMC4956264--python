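"""Input-output kernel regression (IOKR).

Learns a linear-in-feature-space map h(v) = M phi(v) approximating the
output feature map psi of a diffusion output kernel, by regularized least
squares; the predicted output-kernel value of a protein pair is the inner
product <h(u), h(v)>. Two modes:

- supervised: squared loss on the l labeled points + lambda1 ||M||_F^2
- semi-supervised: adds lambda2 * trace(h_M L_Xn h_M^T), a smoothness
  penalty over labeled + unlabeled inputs, with L_Xn = exp(-beta (D_n -
  K_Xn)) built from the input kernel over all n points (D_n = diagonal of
  row sums). A ``laplacian_variant`` switch replaces the exponential by the
  raw Laplacian D_n - K_Xn for sensitivity analysis.

Everything is solved in dual form: with J selecting the labeled columns and
U = J J^T, the coefficient matrix B = J^T (K_n U + lambda1 I + lambda2 L
K_n ... ) solves the stationarity condition, and the predicted kernel for
test inputs with kernel columns kappa is kappa_u^T B^T K_Y B kappa_v. Both
closed forms are certified against direct numerical minimization of the
primal objectives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import KernelMatrix

__all__ = [
    "IOKRModel",
    "fit_iokr_supervised",
    "fit_iokr_semisupervised",
    "iokr_pair_scores",
    "predict_kernel_block",
    "threshold_predictions",
    "smoothness_operator",
]

_JITTER = 1e-10


def _as_array(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def smoothness_operator(
    K_Xn: np.ndarray, beta: float = 1.0, *, laplacian_variant: bool = False
) -> np.ndarray:
    """Penalty operator over the n inputs: exp(-beta (D_n - K_Xn)) by default.

    D_n is the diagonal matrix of row sums of the input kernel. With
    ``laplacian_variant`` the raw D_n - K_Xn is returned instead.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    K_Xn = np.asarray(K_Xn, dtype=float)
    L = np.diag(K_Xn.sum(axis=1)) - K_Xn
    if laplacian_variant:
        return L
    w, V = np.linalg.eigh(-beta * L)
    return (V * np.exp(w)) @ V.T


@dataclass
class IOKRModel:
    """Fitted IOKR predictor in dual form.

    ``B`` is the l x n dual coefficient matrix: h(v) = Psi B kappa_n(v)
    where kappa_n(v) holds the input-kernel values of v against all n
    training inputs and Psi the (implicit) output feature vectors of the l
    labeled points. Pair scores only ever need B^T K_Y B.
    """

    B: np.ndarray = field(repr=False)
    K_Y: np.ndarray = field(repr=False)
    lambda1: float
    lambda2: float = 0.0
    beta: float = 1.0
    semi_supervised: bool = False
    n_labeled: int = 0
    n_total: int = 0
    train_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self._Q = self.B.T @ self.K_Y @ self.B  # n x n scoring core

    @property
    def scoring_core(self) -> np.ndarray:
        return self._Q


def fit_iokr_supervised(
    K_X: KernelMatrix | np.ndarray,
    K_Y: KernelMatrix | np.ndarray,
    lambda1: float,
) -> IOKRModel:
    """Closed-form ridge solution of the supervised objective.

    min_M sum_i ||M phi(v_i) - psi(v_i)||^2 + lambda1 ||M||_F^2, whose dual
    coefficient matrix is B = (K_X + lambda1 I)^-1; the predicted training
    block is then K_X B^T K_Y B K_X = G K_Y G with G = K_X (K_X + l1 I)^-1.
    """
    if lambda1 <= 0:
        raise ValueError("lambda1 must be strictly positive")
    KX = _as_array(K_X)
    KYm = _as_array(K_Y)
    if KX.shape != KYm.shape:
        raise ValueError("input and output kernel dimensions must agree")
    l = KX.shape[0]
    ids = list(K_X.entity_ids) if isinstance(K_X, KernelMatrix) else None
    A = KX + lambda1 * np.eye(l)
    B = _solve_sym(A, np.eye(l))
    return IOKRModel(
        B=B, K_Y=KYm, lambda1=lambda1, semi_supervised=False,
        n_labeled=l, n_total=l, train_ids=ids,
    )


def fit_iokr_semisupervised(
    K_Xn: KernelMatrix | np.ndarray,
    K_Y: KernelMatrix | np.ndarray,
    lambda1: float,
    lambda2: float,
    beta: float = 1.0,
    *,
    laplacian_variant: bool = False,
) -> IOKRModel:
    """Closed form of the semi-supervised objective.

    The first l indices of K_Xn must be the labeled points (K_Y is l x l).
    Stationarity of the objective gives B = J^T (K_n U + lambda1 I +
    lambda2 K_n L)^-1 with U = diag(1_l, 0_u) and L the smoothness
    operator; lambda2 = 0 recovers the supervised solution exactly.
    """
    if lambda1 <= 0:
        raise ValueError("lambda1 must be strictly positive")
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    Kn = _as_array(K_Xn)
    KYm = _as_array(K_Y)
    n = Kn.shape[0]
    l = KYm.shape[0]
    if l > n:
        raise ValueError("more labeled points than rows in K_Xn")
    ids = list(K_Xn.entity_ids) if isinstance(K_Xn, KernelMatrix) else None
    L = smoothness_operator(Kn, beta, laplacian_variant=laplacian_variant)
    U = np.zeros((n, n))
    U[:l, :l] = np.eye(l)
    A = Kn @ U + lambda1 * np.eye(n) + lambda2 * Kn @ L
    # A is nonsymmetric in general; LU solve, least-squares fallback when the
    # system is numerically singular (e.g. duplicated inputs in K_Xn)
    try:
        Binv = scipy.linalg.solve(A, np.eye(n))
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        jitter = _JITTER * max(1.0, np.abs(A).max())
        Binv = np.linalg.lstsq(A + jitter * np.eye(n), np.eye(n), rcond=None)[0]
    B = Binv[:l, :]  # J^T picks the labeled rows
    return IOKRModel(
        B=B, K_Y=KYm, lambda1=lambda1, lambda2=lambda2, beta=beta,
        semi_supervised=True, n_labeled=l, n_total=n, train_ids=ids,
    )


def _solve_sym(A: np.ndarray, Bmat: np.ndarray) -> np.ndarray:
    """Symmetric solve with a small jitter retry on near-singular systems."""
    try:
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), Bmat)
    except scipy.linalg.LinAlgError:
        try:
            return scipy.linalg.solve(
                A + _JITTER * np.eye(A.shape[0]), Bmat, assume_a="sym"
            )
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular IOKR system: {exc}") from exc


def iokr_pair_scores(
    model: IOKRModel, kx_u: np.ndarray, kx_v: np.ndarray | None = None
) -> np.ndarray | float:
    """Predicted output-kernel values <h(u), h(v)>.

    ``kx_u`` (and ``kx_v``) hold input-kernel columns of the test proteins
    against the n training inputs; 1-D inputs give a scalar, 2-D inputs
    (columns stacked as rows) give the full test x test block.
    """
    Q = model.scoring_core
    ku = np.atleast_2d(np.asarray(kx_u, dtype=float))
    kv = ku if kx_v is None else np.atleast_2d(np.asarray(kx_v, dtype=float))
    if ku.shape[1] != Q.shape[0] or kv.shape[1] != Q.shape[0]:
        raise ValueError("kernel columns must align with the training inputs")
    block = ku @ Q @ kv.T
    if np.asarray(kx_u).ndim == 1 and (kx_v is None or np.asarray(kx_v).ndim == 1):
        return float(block[0, 0])
    return block


def predict_kernel_block(model: IOKRModel, K_test_train: np.ndarray) -> np.ndarray:
    """Symmetric predicted kernel block for test proteins (rows = columns)."""
    block = iokr_pair_scores(model, K_test_train)
    return (block + block.T) / 2.0


def threshold_predictions(scores: np.ndarray, theta: float) -> np.ndarray:
    """Binarize a predicted kernel block: edge iff score > theta.

    Output is symmetric with a zero diagonal.
    """
    S = np.asarray(scores, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("scores must be finite")
    A = (S > theta).astype(np.int8)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0)
    return A
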