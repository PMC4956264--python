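"""Multiple kernel learning: nonnegative mixture weights over a kernel bank.

Four strategies are provided: uniform weights (UNIMKL), weights proportional
to independent centered kernel-target alignments (ALIGN), joint alignment
maximization solved as a nonnegative quadratic program (ALIGNF), and a
sparsity-seeking l_p-norm penalized alignment objective solved by path
following in p (predictor-corrector with warm starts, p decreasing from 2
toward 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .kernels import KernelMatrix, center_kernel, centered_alignment

__all__ = [
    "KernelBank",
    "MKLWeights",
    "combine_kernels",
    "uniform_weights",
    "align_weights",
    "alignf_weights",
    "pnorm_path_weights",
]

_JITTER = 1e-10


@dataclass
class KernelBank:
    """r kernels over one shared entity index."""

    kernels: list[KernelMatrix]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("empty kernel bank")
        ids = self.kernels[0].entity_ids
        for K in self.kernels[1:]:
            if K.entity_ids != ids:
                raise ValueError("all bank kernels must share the entity index")
        if not self.names:
            self.names = [f"K{i}" for i in range(len(self.kernels))]
        if len(self.names) != len(self.kernels):
            raise ValueError("one name per kernel required")

    @property
    def r(self) -> int:
        return len(self.kernels)

    @property
    def entity_ids(self) -> list[str]:
        return self.kernels[0].entity_ids

    def stacked(self) -> np.ndarray:
        return np.stack([K.values for K in self.kernels])


@dataclass
class MKLWeights:
    """Nonnegative mixture weights mu with method provenance."""

    mu: np.ndarray
    method: str
    names: list[str] = field(default_factory=list)
    alignments: np.ndarray | None = None        # per-kernel target alignments
    align_gram: np.ndarray | None = None        # <K_qc, K_lc>_F matrix (ALIGNF)
    achieved_alignment: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(self.mu < -1e-12):
            raise ValueError("mixture weights must be nonnegative")
        self.mu = np.clip(self.mu, 0.0, None)


def combine_kernels(bank: KernelBank, weights: MKLWeights | np.ndarray) -> KernelMatrix:
    """Weighted sum of the bank kernels; PSD is preserved for mu >= 0."""
    mu = weights.mu if isinstance(weights, MKLWeights) else np.asarray(weights, float)
    if mu.shape != (bank.r,):
        raise ValueError("need one weight per kernel")
    if np.any(mu < 0):
        raise ValueError("mixture weights must be nonnegative")
    K = np.tensordot(mu, bank.stacked(), axes=1)
    return KernelMatrix(list(bank.entity_ids), K, check_psd=False)


def uniform_weights(bank: KernelBank) -> MKLWeights:
    """UNIMKL: mu_q = 1 for all kernels (plain sum)."""
    return MKLWeights(np.ones(bank.r), "unimkl", list(bank.names))


def _target_alignments(bank: KernelBank, K_Y, center_target: bool) -> np.ndarray:
    return np.array(
        [centered_alignment(K, K_Y, center_target=center_target) for K in bank.kernels]
    )


def align_weights(
    bank: KernelBank, K_Y: KernelMatrix | np.ndarray, *, center_target: bool = True
) -> MKLWeights:
    """ALIGN: mu_q proportional to the centered alignment rho(K_q, K_Y).

    Negative alignments are clamped to zero; weights normalized to unit sum.
    """
    rho = _target_alignments(bank, K_Y, center_target)
    mu = np.clip(rho, 0.0, None)
    total = mu.sum()
    if total <= 0:
        raise ValueError("all kernel-target alignments are nonpositive")
    return MKLWeights(mu / total, "align", list(bank.names), alignments=rho)


def _centered_stack(bank: KernelBank) -> np.ndarray:
    return np.stack([center_kernel(K.values) for K in bank.kernels])


def alignf_weights(
    bank: KernelBank, K_Y: KernelMatrix | np.ndarray, *, center_target: bool = True
) -> MKLWeights:
    """ALIGNF: maximize the alignment of the mixture kernel with the target.

    max_mu (mu^T a)^2 / (mu^T M mu) over ||mu||_2 = 1, mu >= 0, with
    a_q = <K_qc, K_Y>_F and M_ql = <K_qc, K_lc>_F. Reduces to the
    nonnegative QP  min_v v^T M v - 2 v^T a, v >= 0, followed by
    normalization mu = v / ||v||_2; solved as NNLS on the Cholesky factor.
    """
    KY = K_Y.values if isinstance(K_Y, KernelMatrix) else np.asarray(K_Y, float)
    KYc = center_kernel(KY) if center_target else KY
    Cs = _centered_stack(bank)
    a = np.tensordot(Cs, KYc, axes=([1, 2], [0, 1]))
    M = np.tensordot(Cs, Cs, axes=([1, 2], [1, 2]))
    M = M + _JITTER * np.trace(M) * np.eye(bank.r)
    try:
        R = np.linalg.cholesky(M).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("alignment Gram matrix not positive definite") from exc
    # v^T M v - 2 v^T a == ||R v - R^-T a||^2 - const
    b = scipy.linalg.solve_triangular(R.T, a, lower=True)
    v, _ = scipy.optimize.nnls(R, b)
    nrm = np.linalg.norm(v)
    if nrm <= 0:
        raise ValueError("ALIGNF produced the zero solution (all alignments <= 0)")
    mu = v / nrm
    Kmu = np.tensordot(mu, np.stack([K.values for K in bank.kernels]), axes=1)
    achieved = centered_alignment(Kmu, KY, center_target=center_target)
    return MKLWeights(
        mu, "alignf", list(bank.names),
        alignments=a, align_gram=M, achieved_alignment=achieved,
    )


def _pnorm_objective(mu: np.ndarray, a, mu0, lambda1, lambda2, p) -> float:
    return float(
        lambda1 * np.sum((mu - mu0) ** 2) + lambda2 * np.sum(mu**p) - np.sum(mu * a)
    )


def _pnorm_solve_fixed_p(
    a: np.ndarray, mu0: np.ndarray, lambda1: float, lambda2: float, p: float,
    mu_init: np.ndarray, tol: float, max_iter: int = 200,
) -> np.ndarray:
    """Corrector: projected Newton on the separable per-coordinate problems.

    Each coordinate minimizes lambda1 (mu - mu0_i)^2 + lambda2 mu^p - a_i mu
    over mu >= 0 (convex for p >= 1).
    """
    mu = np.maximum(mu_init.copy(), 0.0)
    eps = 1e-12
    for _ in range(max_iter):
        g = 2 * lambda1 * (mu - mu0) + lambda2 * p * np.maximum(mu, eps) ** (p - 1) - a
        h = 2 * lambda1 + lambda2 * p * (p - 1) * np.maximum(mu, eps) ** (p - 2)
        step = g / h
        mu_new = np.maximum(mu - step, 0.0)
        if np.max(np.abs(mu_new - mu)) < tol:
            mu = mu_new
            break
        mu = mu_new
    else:
        # Newton stalled (can happen for p near 1 at the boundary); polish
        # each coordinate by bounded scalar minimization
        for i in range(len(mu)):
            res = scipy.optimize.minimize_scalar(
                lambda t: lambda1 * (t - mu0[i]) ** 2
                + lambda2 * max(t, 0.0) ** p - a[i] * t,
                bounds=(0.0, max(1.0, 10 * abs(a[i]) / (2 * lambda1))),
                method="bounded",
            )
            mu[i] = max(res.x, 0.0)
    # zero-gradient coordinates pinned at the boundary
    g = 2 * lambda1 * (mu - mu0) + lambda2 * p * np.maximum(mu, eps) ** (p - 1) - a
    mu[(mu <= eps) & (g > 0)] = 0.0
    return mu


def pnorm_path_weights(
    bank: KernelBank,
    K_Y: KernelMatrix | np.ndarray,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    *,
    p_schedule: np.ndarray | None = None,
    sparsity_target: float | None = None,
    mu0: np.ndarray | None = None,
    tol: float = 1e-8,
    center_target: bool = True,
) -> MKLWeights:
    """l_p-norm penalized kernel-target alignment, path following in p.

    Minimizes  lambda1 ||mu - mu0||^2 + lambda2 sum_i mu_i^p - sum_i mu_i a_i
    over mu >= 0 for a decreasing schedule of p (default 2.0 -> 1.01 in 20
    geometric steps), warm-starting each solve from the previous p
    (predictor) and correcting with projected Newton. Stops early once the
    fraction of near-zero weights reaches ``sparsity_target``. At p = 2 with
    mu0 = 0 the solution is the closed form mu_i = max(0, a_i / (2 (lambda1
    + lambda2))).
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("lambda1 and lambda2 must be positive")
    r = bank.r
    mu0 = np.zeros(r) if mu0 is None else np.asarray(mu0, dtype=float)
    if p_schedule is None:
        p_schedule = np.geomspace(2.0, 1.01, 20)
    p_schedule = np.asarray(p_schedule, dtype=float)
    if np.any(np.diff(p_schedule) > 0) or p_schedule[0] > 2.0 + 1e-9:
        raise ValueError("p schedule must decrease from <= 2 toward 1")
    KY = K_Y.values if isinstance(K_Y, KernelMatrix) else np.asarray(K_Y, float)
    KYc = center_kernel(KY) if center_target else KY
    Cs = _centered_stack(bank)
    a = np.tensordot(Cs, KYc, axes=([1, 2], [0, 1]))
    # normalize alignments to unit scale so lambda defaults are meaningful
    scale = np.abs(a).max()
    if scale > 0:
        a = a / scale
    mu = np.maximum(a / (2 * (lambda1 + lambda2)), 0.0)  # exact at p = 2
    path = []
    for p in p_schedule:
        mu = _pnorm_solve_fixed_p(a, mu0, lambda1, lambda2, p, mu, tol)
        path.append((float(p), mu.copy()))
        if sparsity_target is not None and mu.max() > 0:
            frac_zero = np.mean(mu < 1e-6 * mu.max())
            if frac_zero >= sparsity_target:
                break
    if mu.max() <= 0:
        raise ValueError("p-norm path collapsed to the zero solution")
    return MKLWeights(
        mu, "pnorm", list(bank.names), alignments=a,
        extras={"path": path, "mu0": mu0, "lambda1": lambda1, "lambda2": lambda2},
    )
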