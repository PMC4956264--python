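import numpy as np
import pytest

from ppinet.kernels import KernelMatrix, center_kernel, centered_alignment
from ppinet.mkl import (
    KernelBank,
    MKLWeights,
    align_weights,
    alignf_weights,
    combine_kernels,
    pnorm_path_weights,
    uniform_weights,
)

from .conftest import kernel, rand_psd


def _bank(mats):
    ids = [f"p{i}" for i in range(mats[0].shape[0])]
    return KernelBank([KernelMatrix(ids, M, check_psd=False) for M in mats])


def _grid_best_alignment(bank, KY, n=400):
    """Dense search over the nonnegative unit sphere (r = 2 or 3)."""
    r = bank.r
    best, best_mu = -2.0, None
    if r == 2:
        for t in np.linspace(0, np.pi / 2, n):
            mu = np.array([np.cos(t), np.sin(t)])
            a = centered_alignment(combine_kernels(bank, mu).values, KY)
            if a > best:
                best, best_mu = a, mu
    elif r == 3:
        for t in np.linspace(0, np.pi / 2, n):
            for s in np.linspace(0, np.pi / 2, n):
                mu = np.array(
                    [np.cos(t) * np.cos(s), np.cos(t) * np.sin(s), np.sin(t)]
                )
                a = centered_alignment(combine_kernels(bank, mu).values, KY)
                if a > best:
                    best, best_mu = a, mu
    else:
        raise ValueError("grid oracle supports r in {2, 3}")
    return best, best_mu


class TestCombine:
    def test_unit_weights_plain_sum(self, rng):
        mats = [rand_psd(4, rng) for _ in range(3)]
        bank = _bank(mats)
        out = combine_kernels(bank, uniform_weights(bank))
        assert np.allclose(out.values, sum(mats))

    def test_one_hot(self, rng):
        mats = [rand_psd(4, rng) for _ in range(3)]
        bank = _bank(mats)
        out = combine_kernels(bank, np.array([0.0, 1.0, 0.0]))
        assert np.allclose(out.values, mats[1])

    def test_zero_weights(self, rng):
        bank = _bank([rand_psd(3, rng) for _ in range(2)])
        assert np.allclose(combine_kernels(bank, np.zeros(2)).values, 0.0)

    def test_negative_weight_rejected(self, rng):
        bank = _bank([rand_psd(3, rng) for _ in range(2)])
        with pytest.raises(ValueError):
            combine_kernels(bank, np.array([1.0, -0.5]))

    def test_psd_preserved(self, rng):
        bank = _bank([rand_psd(5, rng) for _ in range(4)])
        mu = np.abs(rng.normal(size=4))
        out = combine_kernels(bank, mu)
        assert np.linalg.eigvalsh(out.values).min() >= -1e-10


class TestAlign:
    def test_identical_kernels_equal_weights(self, rng):
        K = rand_psd(5, rng)
        bank = _bank([K.copy() for _ in range(3)])
        w = align_weights(bank, rand_psd(5, rng))
        assert np.allclose(w.mu, 1.0 / 3)

    def test_target_plus_orthogonal(self):
        a = np.array([1.0, -1.0, 0.0])
        b = np.array([1.0, 1.0, -2.0]) / np.sqrt(3)
        KY = np.outer(a, a)
        bank = _bank([KY.copy(), np.outer(b, b)])
        w = align_weights(bank, KY)
        assert np.allclose(w.mu, [1.0, 0.0], atol=1e-12)

    def test_proportional_to_alignments(self, rng):
        mats = [rand_psd(6, rng) for _ in range(3)]
        KY = rand_psd(6, rng)
        bank = _bank(mats)
        w = align_weights(bank, KY)
        rho = np.array([max(centered_alignment(M, KY), 0.0) for M in mats])
        assert np.allclose(w.mu, rho / rho.sum())

    def test_all_nonpositive_rejected(self):
        a = np.array([1.0, -1.0, 0.0])
        b = np.array([1.0, 1.0, -2.0]) / np.sqrt(3)
        bank = _bank([np.outer(b, b)])
        with pytest.raises(ValueError):
            align_weights(bank, np.outer(a, a))


class TestAlignF:
    def test_single_kernel_unit_weight(self, rng):
        bank = _bank([rand_psd(4, rng)])
        w = alignf_weights(bank, rand_psd(4, rng))
        assert np.allclose(w.mu, [1.0])

    def test_target_plus_orthogonal_grid_oracle(self):
        a = np.array([1.0, -1.0, 0.0])
        b = np.array([1.0, 1.0, -2.0]) / np.sqrt(3)
        KY = np.outer(a, a)
        bank = _bank([KY.copy(), np.outer(b, b)])
        w = alignf_weights(bank, KY)
        assert np.allclose(w.mu, [1.0, 0.0], atol=1e-6)

    @pytest.mark.parametrize("seed,r", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_matches_dense_grid_search(self, seed, r):
        rng = np.random.default_rng(seed)
        m = 6
        bank = _bank([rand_psd(m, rng) for _ in range(r)])
        KY = rand_psd(m, rng)
        w = alignf_weights(bank, KY)
        grid_best, _ = _grid_best_alignment(bank, KY, n=250 if r == 3 else 4000)
        assert w.achieved_alignment >= grid_best - 1e-3
        assert abs(w.achieved_alignment - grid_best) < 1e-3

    def test_unit_norm(self, rng):
        bank = _bank([rand_psd(5, rng) for _ in range(3)])
        w = alignf_weights(bank, rand_psd(5, rng))
        assert np.linalg.norm(w.mu) == pytest.approx(1.0)

    def test_beats_singles_and_uniform(self, rng):
        bank = _bank([rand_psd(6, rng) for _ in range(3)])
        KY = rand_psd(6, rng)
        w = alignf_weights(bank, KY)
        singles = [centered_alignment(K.values, KY) for K in bank.kernels]
        unif = centered_alignment(combine_kernels(bank, uniform_weights(bank)).values, KY)
        assert w.achieved_alignment >= max(singles) - 1e-9
        assert w.achieved_alignment >= unif - 1e-9

    def test_kkt_conditions(self, rng):
        # QP: min v^T M v - 2 v^T a, v >= 0; KKT: grad >= 0, v >= 0, v.grad = 0
        bank = _bank([rand_psd(6, rng) for _ in range(4)])
        KY = rand_psd(6, rng)
        w = alignf_weights(bank, KY)
        M, a = w.align_gram, w.alignments
        # KKT is checked on the unnormalized QP solution (scale-covariant)
        import scipy.optimize

        R = np.linalg.cholesky(M).T
        b = np.linalg.solve(R.T, a)
        v, _ = scipy.optimize.nnls(R, b)
        grad = 2 * (M @ v - a)
        assert np.all(grad >= -1e-6 * max(1, np.abs(a).max()))
        assert np.all(v >= 0)
        assert abs(v @ grad) <= 1e-6 * max(1, abs(v @ a))


class TestPnormPath:
    def test_p2_closed_form(self, rng):
        bank = _bank([rand_psd(6, rng) for _ in range(4)])
        KY = rand_psd(6, rng)
        lam1, lam2 = 0.8, 0.4
        w = pnorm_path_weights(bank, KY, lam1, lam2, p_schedule=np.array([2.0]))
        a = w.alignments
        assert np.allclose(w.mu, np.maximum(0.0, a / (2 * (lam1 + lam2))), atol=1e-10)

    def test_p2_matches_projected_gradient_oracle(self, rng):
        bank = _bank([rand_psd(6, rng) for _ in range(3)])
        KY = rand_psd(6, rng)
        lam1, lam2, p = 1.0, 0.5, 2.0
        w = pnorm_path_weights(bank, KY, lam1, lam2, p_schedule=np.array([2.0]))
        a = w.alignments
        mu = np.zeros(3)
        for _ in range(20000):  # projected gradient descent oracle
            g = 2 * lam1 * mu + lam2 * p * mu ** (p - 1) - a
            mu = np.maximum(mu - 1e-3 * g, 0.0)
        assert np.allclose(w.mu, mu, atol=1e-6)

    def test_equal_alignments_equal_weights(self, rng):
        K = rand_psd(5, rng)
        bank = _bank([K.copy() for _ in range(4)])
        KY = rand_psd(5, rng)
        w = pnorm_path_weights(bank, KY, 1.0, 1.0)
        assert np.allclose(w.mu, w.mu[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_active_set_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        bank = _bank([rand_psd(6, rng) for _ in range(6)])
        KY = rand_psd(6, rng)
        w = pnorm_path_weights(bank, KY, 0.5, 0.5)
        counts = [int(np.sum(mu > 1e-6 * max(mu.max(), 1e-300)))
                  for _, mu in w.extras["path"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_path_matches_per_p_independent_solves(self, rng):
        # warm-started path == cold solves at each p (convex, unique optimum)
        from ppinet.mkl import _pnorm_solve_fixed_p

        bank = _bank([rand_psd(6, rng) for _ in range(4)])
        KY = rand_psd(6, rng)
        lam1 = lam2 = 1.0
        w = pnorm_path_weights(bank, KY, lam1, lam2)
        a = w.alignments
        for p, mu in w.extras["path"][::5]:
            cold = _pnorm_solve_fixed_p(
                a, np.zeros(len(a)), lam1, lam2, p,
                np.full(len(a), 0.5), tol=1e-10,
            )
            assert np.allclose(mu, cold, atol=1e-5)

    def test_invalid_lambdas(self, rng):
        bank = _bank([rand_psd(4, rng)])
        with pytest.raises(ValueError):
            pnorm_path_weights(bank, rand_psd(4, rng), 0.0, 1.0)

    def test_sparsity_target_stops_early(self, rng):
        bank = _bank([rand_psd(6, rng) for _ in range(6)])
        KY = rand_psd(6, rng)
        w = pnorm_path_weights(bank, KY, 0.5, 0.5, sparsity_target=0.3)
        frac_zero = np.mean(w.mu < 1e-6 * w.mu.max())
        # either reached the target or exhausted the schedule
        assert frac_zero >= 0.3 or len(w.extras["path"]) == 20


class TestWeightsInvariants:
    @pytest.mark.parametrize("method", ["uniform", "align", "alignf", "pnorm"])
    def test_nonnegative_and_psd(self, method, rng):
        bank = _bank([rand_psd(6, rng) for _ in range(3)])
        KY = rand_psd(6, rng)
        w = {
            "uniform": lambda: uniform_weights(bank),
            "align": lambda: align_weights(bank, KY),
            "alignf": lambda: alignf_weights(bank, KY),
            "pnorm": lambda: pnorm_path_weights(bank, KY),
        }[method]()
        assert np.all(w.mu >= 0)
        K = combine_kernels(bank, w)
        assert np.linalg.eigvalsh(K.values).min() >= -1e-9

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            MKLWeights(np.array([0.5, -0.1]), "x")
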