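"""Overcomplete analytic dictionaries and K-SVD refinement.

The analytic construction is an overcomplete discrete cosine transform (DCT):
entry ``(i, j)`` is ``cos(pi * i * j / cols)``; non-constant columns are
mean-centered and every column is scaled to unit l2 norm.  Such a dictionary
can be built at any overcomplete size, independent of how many training
samples exist — the property that motivates using it instead of a dictionary
made of the training samples themselves.

K-SVD then adapts the dictionary to a training set: it alternates sparse
coding of all samples (OMP at a fixed sparse factor) with per-atom rank-one
SVD updates of each used atom and its nonzero coefficients, driving down the
total squared reconstruction error  sum_i ||x_i - D alpha_i||^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InputError
from .sparse_coding import CodingBudget, omp_solve

logger = logging.getLogger(__name__)

_NORM_ATOL = 1e-10


@dataclass
class Dictionary:
    """Atom matrix with unit-norm columns.

    ``split_row`` (optional) marks the boundary between a signal block
    (first ``split_row`` rows, the part coded against) and a label block
    (remaining rows, the part that carries class information) for
    label-augmented dictionaries.
    """

    atoms: np.ndarray
    split_row: int | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise InputError("atoms must be a 2-D matrix")
        if not np.all(np.isfinite(self.atoms)):
            raise InputError("atoms contain non-finite values")
        if self.split_row is not None and not 0 < self.split_row < self.rows:
            raise ConfigurationError(f"split_row {self.split_row} outside (0, {self.rows})")

    @property
    def rows(self) -> int:
        return self.atoms.shape[0]

    @property
    def cols(self) -> int:
        return self.atoms.shape[1]

    @property
    def upper(self) -> np.ndarray:
        """Signal block (all rows when no split is set)."""
        return self.atoms if self.split_row is None else self.atoms[: self.split_row]

    @property
    def lower(self) -> np.ndarray:
        """Label block; empty when no split is set."""
        if self.split_row is None:
            return self.atoms[:0]
        return self.atoms[self.split_row :]

    def copy(self) -> "Dictionary":
        return Dictionary(self.atoms.copy(), self.split_row)


@dataclass(frozen=True)
class LearningSchedule:
    """K-SVD hyperparameters.

    ``n_iterations`` full sweeps (coding + atom updates); ``sparse_factor`` is
    the OMP budget used during learning; ``unused_atom_policy`` controls what
    happens to atoms no training signal selected in a sweep.
    """

    n_iterations: int = 30
    sparse_factor: int = 5
    unused_atom_policy: Literal["replace_with_worst_signal", "keep"] = "replace_with_worst_signal"

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ConfigurationError("n_iterations must be >= 0")
        if self.sparse_factor < 1:
            raise ConfigurationError("sparse_factor must be >= 1")
        if self.unused_atom_policy not in ("replace_with_worst_signal", "keep"):
            raise ConfigurationError(f"unknown unused_atom_policy {self.unused_atom_policy!r}")


def make_dct_dictionary(rows: int, cols: int | None = None, split_row: int | None = None) -> Dictionary:
    """Overcomplete DCT dictionary of shape ``rows x cols`` (default cols = 2*rows).

    Raises
    ------
    ConfigurationError
        If ``cols <= rows`` (the dictionary would not be overcomplete).
    """
    if cols is None:
        cols = 2 * rows
    if rows < 1:
        raise ConfigurationError("rows must be >= 1")
    if cols <= rows:
        raise ConfigurationError(f"cols ({cols}) must exceed rows ({rows}) for overcompleteness")
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    atoms = np.cos(np.pi * i * j / cols)
    centered = atoms - atoms.mean(axis=0, keepdims=True)
    # Mean-center every non-constant column; keep the raw column where
    # centering would annihilate it (rows == 1, or a constant column).
    keep = np.linalg.norm(centered, axis=0) <= 1e-12
    centered[:, keep] = atoms[:, keep]
    centered[:, 0] = atoms[:, 0]
    atoms = centered / np.linalg.norm(centered, axis=0, keepdims=True)
    return Dictionary(atoms, split_row=split_row)


def make_low_coherence_dictionary(
    rows: int,
    cols: int,
    target: float = 0.35,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 6000,
) -> Dictionary:
    """Random overcomplete dictionary with mutual coherence below ``target``.

    Starts from a Gaussian draw and alternates clipping the off-diagonal Gram
    entries at ``0.95 * target`` with a rank-``rows`` spectral projection.
    Greedy sparse coders come with recovery guarantees only for incoherent
    dictionaries, which plain random draws at small sizes are not; this
    constructor provides controlled planted-recovery benchmarks.

    The requested target must be reachable: the Welch bound
    sqrt((cols-rows) / (rows*(cols-1))) is a hard floor.
    """
    if cols <= rows:
        raise ConfigurationError(f"cols ({cols}) must exceed rows ({rows})")
    welch = np.sqrt((cols - rows) / (rows * (cols - 1.0)))
    if target <= welch:
        raise ConfigurationError(f"coherence target {target} is below the Welch bound {welch:.3f}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    D = rng.normal(size=(rows, cols))
    D /= np.linalg.norm(D, axis=0)
    for _ in range(max_iter):
        gram = D.T @ D
        if np.abs(gram - np.eye(cols)).max() < target:
            break
        clipped = np.clip(gram, -0.95 * target, 0.95 * target)
        np.fill_diagonal(clipped, 1.0)
        u, s, _ = np.linalg.svd(clipped)
        D = (u[:, :rows] * np.sqrt(s[:rows])).T
        D /= np.linalg.norm(D, axis=0)
    else:
        logger.warning("coherence target %.3f not reached in %d iterations", target, max_iter)
    return Dictionary(D)


def reconstruction_objective(signals: np.ndarray, dictionary: Dictionary, budget: CodingBudget) -> float:
    """Total squared reconstruction error of freshly coded signals.

    Evaluates  sum_i ||x_i - D alpha_i||^2  with each ``alpha_i`` obtained by
    OMP against the current dictionary (signals as rows of ``signals``).
    """
    total = 0.0
    for x in signals:
        code = omp_solve(x, dictionary, budget)
        dense = dictionary.atoms[:, code.support] @ code.coefficients if code.n_nonzero else 0.0
        total += float(np.sum((x - dense) ** 2))
    return total


def ksvd_learn(
    training: Iterable[np.ndarray] | np.ndarray,
    initial: Dictionary,
    schedule: LearningSchedule = LearningSchedule(),
    *,
    return_history: bool = False,
):
    """Refine ``initial`` with K-SVD on a training set.

    Parameters
    ----------
    training : array-like of shape (r, rows)
        Training signals as rows; lengths must equal ``initial.rows``.
    initial : Dictionary
        Starting dictionary (its atoms are copied, not mutated).
    schedule : LearningSchedule
        Iteration count, coding sparse factor and unused-atom policy.
    return_history : bool
        When true also return the per-iteration objective values
        (index 0 = objective of the initial dictionary).

    Returns
    -------
    Dictionary, or (Dictionary, list of float) when ``return_history``.
    """
    X = np.atleast_2d(np.asarray(training, dtype=np.float64))
    if X.size == 0:
        raise InputError("training set is empty")
    if X.shape[1] != initial.rows:
        raise InputError(f"training signal length {X.shape[1]} != dictionary rows {initial.rows}")
    if not np.all(np.isfinite(X)):
        raise InputError("training signals contain non-finite values")

    D = initial.atoms.copy()
    budget = CodingBudget(schedule.sparse_factor)

    # Initial coding stage.
    A = np.zeros((D.shape[1], X.shape[0]))  # coefficients, atoms x samples
    for idx, x in enumerate(X):
        code = omp_solve(x, D, budget)
        A[code.support, idx] = code.coefficients
    E = X.T - D @ A  # residual matrix, rows x samples
    history = [float(np.sum(E**2))]

    for _ in range(schedule.n_iterations):
        # Atom-update stage: rank-one refit of each used atom.  The optimal
        # rank-one approximation never increases the error for the fixed
        # supports, so this stage is monotone.
        unused: list[int] = []
        for j in range(D.shape[1]):
            using = np.flatnonzero(A[j])
            if using.size == 0:
                unused.append(j)
                continue
            # Error restricted to the samples using atom j, with its own
            # contribution added back.
            E_j = E[:, using] + np.outer(D[:, j], A[j, using])
            u, s, vt = np.linalg.svd(E_j, full_matrices=False)
            atom, coefs = u[:, 0], s[0] * vt[0]
            atom, coefs = _fix_sign(atom, coefs)
            E[:, using] = E_j - np.outer(atom, coefs)
            D[:, j] = atom
            A[j, using] = coefs

        # Unused atoms carry zero coefficients, so replacing them leaves the
        # current reconstruction (and objective) untouched.
        if unused and schedule.unused_atom_policy == "replace_with_worst_signal":
            _replace_unused(D, X, A, unused)

        # Coding stage with a warm-start safeguard: a sample keeps its
        # previous code whenever greedy OMP against the updated dictionary
        # would reconstruct it worse, so the objective cannot increase.
        for idx, x in enumerate(X):
            code = omp_solve(x, D, budget)
            approx = D[:, code.support] @ code.coefficients if code.n_nonzero else np.zeros(x.size)
            new_residual = x - approx
            if np.sum(new_residual**2) <= np.sum(E[:, idx] ** 2):
                A[:, idx] = 0.0
                A[code.support, idx] = code.coefficients
                E[:, idx] = new_residual
        history.append(float(np.sum(E**2)))

    learned = Dictionary(D, split_row=initial.split_row)
    if return_history:
        return learned, history
    return learned


def _fix_sign(atom: np.ndarray, coefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force the largest-magnitude atom entry nonnegative (sign convention)."""
    pivot = atom[np.argmax(np.abs(atom))]
    if pivot < 0:
        return -atom, -coefs
    return atom, coefs


def _replace_unused(D: np.ndarray, X: np.ndarray, A: np.ndarray, unused: Sequence[int]) -> None:
    """Replace unused atoms with the worst-reconstructed training signals.

    Each unused atom gets a distinct signal (largest residual first, then the
    next, ...); atoms beyond the number of training signals are left as they
    are.
    """
    residuals = np.linalg.norm(X.T - D @ A, axis=0)
    order = np.argsort(residuals)[::-1]
    for j, sig_idx in zip(unused, order):
        norm = np.linalg.norm(X[sig_idx])
        if norm <= _NORM_ATOL:
            continue
        atom = X[sig_idx] / norm
        D[:, j], _ = _fix_sign(atom, np.zeros(0))
    if len(unused) > len(order):
        logger.debug("%d unused atoms left unchanged (fewer signals than unused atoms)",
                     len(unused) - len(order))


# ---------------------------------------------------------------------------
# Plain-text serialization: a one-line header "rows cols split_row" (split_row
# written as -1 when absent) followed by the atom matrix, one row per line.

def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    path = Path(path)
    split = -1 if dictionary.split_row is None else dictionary.split_row
    with path.open("w") as fh:
        fh.write(f"{dictionary.rows} {dictionary.cols} {split}\n")
        for row in dictionary.atoms:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_dictionary(path: str | Path) -> Dictionary:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise FormatError(f"{path}: expected header 'rows cols split_row'")
        rows, cols, split = (int(v) for v in header)
        atoms = np.loadtxt(fh, ndmin=2)
    if atoms.shape != (rows, cols):
        raise FormatError(f"{path}: matrix shape {atoms.shape} != header ({rows}, {cols})")
    return Dictionary(atoms, split_row=None if split < 0 else split)
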