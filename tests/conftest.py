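import itertools

import numpy as np
import pytest

import cpetsrc as cs


def unit_dictionary(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Random Gaussian dictionary with unit-norm columns."""
    atoms = rng.normal(size=(rows, cols))
    return atoms / np.linalg.norm(atoms, axis=0)


def exhaustive_sparse_support(x: np.ndarray, atoms: np.ndarray, k: int) -> set[int]:
    """Brute-force oracle: the size-k support with minimal least-squares residual."""
    best_support, best_residual = None, np.inf
    for support in itertools.combinations(range(atoms.shape[1]), k):
        sub = atoms[:, support]
        coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
        residual = np.linalg.norm(x - sub @ coef)
        if residual < best_residual:
            best_residual, best_support = residual, support
    return set(best_support)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """Fast low-dimensional synthetic dataset for classifier unit tests."""
    spec = cs.SyntheticSpec(n_per_class=6, length_range=(30, 60), seed=11)
    series, labels = cs.generate(spec)
    return cs.build_dataset(series, labels, target_length=60, class_order=["strong", "weak"])


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale synthetic cohort (24 patients, length 270)."""
    series, labels = cs.generate(cs.SyntheticSpec())
    return cs.build_dataset(series, labels, class_order=["strong", "weak"])
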