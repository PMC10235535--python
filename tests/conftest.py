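import numpy as np
import pytest

from mcmrr.basis import ShapeBasisSet
from mcmrr.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_truth():
    """Noiseless K=3, p=12 ground truth with identifiable bases."""
    return generate(SyntheticSpec(p=12, K_true=3, F_train=40, F_test=4, noise_sigma=0.0, seed=7))


def random_row_orthonormal(rng) -> np.ndarray:
    """Random 2x3 matrix with orthonormal rows (first two rows of a rotation)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q[:2, :]


def random_basis_set(rng, K: int, p: int) -> ShapeBasisSet:
    """Random centered unit-norm bases stacked into a ShapeBasisSet."""
    blocks = []
    for _ in range(K):
        B = rng.normal(size=(3, p))
        B -= B.mean(axis=1, keepdims=True)
        blocks.append(B / np.linalg.norm(B))
    return ShapeBasisSet(B=np.vstack(blocks), K=K, p=p)
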