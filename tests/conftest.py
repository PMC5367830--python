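import numpy as np
import pytest

from ml2motif import MotifSpec, exact_poim, generate_dataset, train_wd_svm
from ml2motif._kmers import seq_to_codes


def one_hot(pattern: str) -> np.ndarray:
    """Deterministic one-hot PWM of an exact motif string."""
    codes = seq_to_codes(pattern)
    r = np.zeros((4, len(pattern)))
    r[codes, np.arange(len(pattern))] = 1.0
    return r


def random_seqs(rng, n, L):
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, L)) for _ in range(n)]


@pytest.fixture(scope="session")
def toy_svm():
    """Small WD-SVM (L=8, degree 3) cheap enough for exhaustive enumeration."""
    data = generate_dataset(60, 8, [MotifSpec("ACG", 3)], 0.5, 0.0, seed=2)
    return train_wd_svm(data, ell_max=3, C=1.0, seed=2)


@pytest.fixture(scope="session")
def cctata_model():
    """WD-SVM trained on the single-motif reference dataset (CCTATA at 11)."""
    data = generate_dataset(2000, 30, [MotifSpec("CCTATA", 11)], 0.5, 0.0, seed=7)
    return train_wd_svm(data, ell_max=8, C=1.0, seed=7)


@pytest.fixture(scope="session")
def cctata_exact_s6(cctata_model):
    """Exact centered order-6 importance matrix of the reference SVM."""
    return exact_poim(cctata_model, k=6, centered=True)
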