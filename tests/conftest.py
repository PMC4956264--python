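import numpy as np
import pytest

from ppinet.kernels import FeatureTable, InteractionNetwork, KernelMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_psd(n: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(n, n))
    return A @ A.T / n


def rand_network(m: int, p: float, rng: np.random.Generator) -> InteractionNetwork:
    A = (rng.random((m, m)) < p).astype(np.int8)
    A = np.triu(A, 1)
    A = A + A.T
    return InteractionNetwork([f"p{i}" for i in range(m)], A)


def kernel(values: np.ndarray, check_psd: bool = False) -> KernelMatrix:
    return KernelMatrix([f"p{i}" for i in range(values.shape[0])], values,
                        check_psd=check_psd)


@pytest.fixture
def small_features(rng):
    return FeatureTable([f"p{i}" for i in range(8)], rng.normal(size=(8, 3)))
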