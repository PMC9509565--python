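import numpy as np
import pytest

from adafilter import CountMatrix, simulate_nb_fixed


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_counts():
    """3 genes x 4 samples, groups (1,1,2,2), one all-zero gene."""
    counts = np.array([
        [5, 7, 9, 11],
        [0, 0, 0, 0],
        [2, 0, 3, 1],
    ])
    return CountMatrix(counts, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"],
                       [1, 1, 2, 2])


@pytest.fixture
def nb_counts():
    """A moderate NB dataset with signal (m=300, n=6+6)."""
    cm, truth = simulate_nb_fixed(m=300, n1=6, n2=6, pi0=0.8, mu0=20,
                                  fold_change=2.5, dispersion=0.15, seed=7)
    return cm, truth


def random_count_matrix(rng, m=20, n=6, max_count=40, n1=None):
    counts = rng.integers(0, max_count, size=(m, n))
    n1 = n // 2 if n1 is None else n1
    groups = [1] * n1 + [2] * (n - n1)
    return CountMatrix(counts, [f"g{i}" for i in range(m)],
                       [f"s{j}" for j in range(n)], groups)
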