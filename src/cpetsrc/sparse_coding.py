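"""Sparsity-constrained signal coding via orthogonal matching pursuit (OMP).

A signal ``x`` of length ``m`` is approximated as ``D @ alpha`` where ``D`` is
an overcomplete dictionary with unit-norm columns (atoms) and ``alpha`` has at
most ``k`` nonzero entries (the sparse factor).  OMP greedily selects the atom
most correlated with the current residual and refits all selected coefficients
by least squares at every step, so the residual stays orthogonal to the chosen
atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

#: Relative tolerance used by the residual-orthogonality contract.
ORTHOGONALITY_RTOL = 1e-8

#: Residual norms below this (relative to the signal norm) count as exact.
_EXACT_RTOL = 1e-12


@dataclass(frozen=True)
class CodingBudget:
    """Stopping rule for a sparse coder.

    Parameters
    ----------
    sparse_factor : int
        Maximum number of atoms ``k`` (>= 1).
    residual_tol : float, optional
        If given, iteration also stops once the residual l2 norm drops to or
        below this value.
    """

    sparse_factor: int
    residual_tol: float | None = None

    def __post_init__(self) -> None:
        if self.sparse_factor < 1:
            raise InputError(f"sparse_factor must be >= 1, got {self.sparse_factor}")
        if self.residual_tol is not None and self.residual_tol < 0:
            raise InputError("residual_tol must be nonnegative")


@dataclass(frozen=True)
class SparseCode:
    """Support indices plus coefficients for one coded signal.

    ``support`` holds 0-based atom indices into a dictionary with
    ``ambient_size`` columns; ``coefficients`` is aligned with ``support``.
    """

    support: np.ndarray
    coefficients: np.ndarray
    ambient_size: int

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.intp)
        coefficients = np.asarray(self.coefficients, dtype=np.float64)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "coefficients", coefficients)
        if support.ndim != 1 or coefficients.ndim != 1:
            raise InputError("support and coefficients must be 1-D")
        if support.size != coefficients.size:
            raise InputError("support and coefficients must have equal length")
        if support.size and (support.min() < 0 or support.max() >= self.ambient_size):
            raise InputError("support index out of range")
        if support.size != np.unique(support).size:
            raise InputError("support indices must be unique")
        if not np.all(np.isfinite(coefficients)):
            raise InputError("coefficients must be finite")

    @property
    def n_nonzero(self) -> int:
        return int(self.support.size)

    def to_dense(self) -> np.ndarray:
        """Full-length coefficient vector ``alpha`` in R^n."""
        alpha = np.zeros(self.ambient_size)
        alpha[self.support] = self.coefficients
        return alpha


def _as_signal(x, name: str = "signal") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 1:
        raise InputError(f"{name} must have length >= 1")
    if not np.all(np.isfinite(x)):
        raise InputError(f"{name} contains non-finite values")
    return x


def omp_solve(signal, dictionary, budget: CodingBudget) -> SparseCode:
    """Greedy sparse coding of ``signal`` against ``dictionary``.

    At each step the atom with the largest absolute correlation with the
    residual is added (ties broken toward the lower index), then the
    coefficients on the current support are refit by least squares.  Stops
    after ``budget.sparse_factor`` atoms, or earlier when the residual norm
    reaches ``budget.residual_tol`` (or is numerically zero).

    Returns
    -------
    SparseCode
        Support and least-squares coefficients; empty for a zero signal.
    """
    x = _as_signal(signal)
    atoms = _atom_matrix(dictionary)
    m, n = atoms.shape
    if m != x.size:
        raise InputError(f"atom length {m} != signal length {x.size}")

    tol = budget.residual_tol
    # A numerically exact reconstruction always stops the iteration, even when
    # no explicit residual tolerance was requested (zero-signal case).
    x_norm = float(np.linalg.norm(x))
    exact_cut = _EXACT_RTOL * max(x_norm, 1.0)
    stop_norm = max(tol, exact_cut) if tol is not None else exact_cut

    support: list[int] = []
    coef = np.zeros(0)
    residual = x.copy()
    for _ in range(min(budget.sparse_factor, n, m)):
        if np.linalg.norm(residual) <= stop_norm:
            break
        corr = atoms.T @ residual
        candidate = int(np.argmax(np.abs(corr)))  # argmax takes the lowest index on ties
        if abs(corr[candidate]) <= exact_cut:
            break
        support.append(candidate)
        sub = atoms[:, support]
        coef = _least_squares(sub, x)
        residual = x - sub @ coef
    return SparseCode(np.array(support, dtype=np.intp), coef, ambient_size=n)


def _least_squares(sub: np.ndarray, x: np.ndarray) -> np.ndarray:
    gram = sub.T @ sub
    rhs = sub.T @ x
    try:
        return np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        logger.warning("singular Gram matrix on support of size %d; using pseudoinverse", sub.shape[1])
        warnings.warn("singular Gram matrix in OMP refit; using pseudoinverse", RuntimeWarning, stacklevel=3)
        return np.linalg.pinv(sub) @ x


def reconstruct(dictionary, code: SparseCode) -> np.ndarray:
    """Linear combination ``D @ alpha`` of the selected atoms."""
    atoms = _atom_matrix(dictionary)
    if code.ambient_size != atoms.shape[1]:
        raise InputError(
            f"code ambient size {code.ambient_size} != dictionary columns {atoms.shape[1]}"
        )
    if code.n_nonzero == 0:
        return np.zeros(atoms.shape[0])
    return atoms[:, code.support] @ code.coefficients


def residual_norm(signal, dictionary, code: SparseCode) -> float:
    """l2 norm of ``x - D @ alpha``; zero iff the reconstruction is exact."""
    x = _as_signal(signal)
    approx = reconstruct(dictionary, code)
    if approx.size != x.size:
        raise InputError(f"atom length {approx.size} != signal length {x.size}")
    return float(np.linalg.norm(x - approx))


def _atom_matrix(dictionary) -> np.ndarray:
    """Accept either a Dictionary object or a raw 2-D array of atoms."""
    atoms = getattr(dictionary, "atoms", dictionary)
    atoms = np.asarray(atoms, dtype=np.float64)
    if atoms.ndim != 2 or atoms.shape[1] < 1:
        raise InputError("dictionary must be a 2-D matrix with >= 1 column")
    if not np.all(np.isfinite(atoms)):
        raise InputError("dictionary contains non-finite values")
    return atoms
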