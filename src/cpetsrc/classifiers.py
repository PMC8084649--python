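"""The two sparse-representation classifiers.

SRC (classic): the dictionary's atoms are the l2-normalized training samples,
grouped into per-class blocks.  An unlabeled sample is sparse-coded against
the whole dictionary and assigned the class whose block reconstructs it with
the smallest residual.  This needs more training samples than the sample
dimension to make the dictionary overcomplete — rarely true for clinical
cohorts.

SRC-AL: training samples are l2-normalized and concatenated with a one-hot
label code; an analytic (overcomplete DCT) dictionary over this augmented
space is refined by K-SVD, so its size is decoupled from the cohort size.
At test time the unlabeled sample is coded against the signal block of the
learned dictionary only, and the label block applied to the sparse code
yields a label vector whose largest-magnitude entry names the class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dictionaries import Dictionary, LearningSchedule, ksvd_learn, make_dct_dictionary
from .errors import ConfigurationError, InputError
from .preprocessing import LabeledDataset, l2_normalize, one_hot
from .sparse_coding import CodingBudget, omp_solve

logger = logging.getLogger(__name__)


@dataclass
class SRCModel:
    """Data-implemented dictionary: one unit-norm column per training sample."""

    dictionary: Dictionary
    class_blocks: dict  # class id -> array of column indices
    class_order: list


@dataclass
class SRCALModel:
    """Label-augmented learned dictionary with signal block of ``m`` rows."""

    learned: Dictionary
    class_order: list
    sparse_factor: int

    @property
    def m(self) -> int:
        return int(self.learned.split_row)

    @property
    def n_classes(self) -> int:
        return self.learned.rows - self.m


def src_fit(data: LabeledDataset) -> SRCModel:
    """Build the SRC dictionary from normalized training samples, grouped by class."""
    if data.n_samples == 0:
        raise InputError("empty training set")
    m = data.length
    atoms = np.empty((m, data.n_samples))
    blocks: dict = {cls: [] for cls in data.class_order}
    col = 0
    for cls in data.class_order:
        for i, label in enumerate(data.labels):
            if label != cls:
                continue
            atoms[:, col] = l2_normalize(data.samples[i])
            blocks[cls].append(col)
            col += 1
    if data.n_samples < m:
        logger.warning(
            "SRC dictionary is not overcomplete (%d samples < dimension %d); "
            "expect degraded performance", data.n_samples, m,
        )
    return SRCModel(
        Dictionary(atoms),
        {cls: np.array(idx, dtype=np.intp) for cls, idx in blocks.items()},
        list(data.class_order),
    )


def src_predict(model: SRCModel, y, budget: CodingBudget, return_residuals: bool = False):
    """Minimum class-restricted reconstruction residual rule.

    Codes the normalized ``y`` against the full dictionary, then for each class
    reconstructs with that class's coefficients only; the class with the
    smallest residual wins (ties -> earlier class in class_order).
    """
    y = l2_normalize(y)
    if y.size != model.dictionary.rows:
        raise InputError(f"sample length {y.size} != model dimension {model.dictionary.rows}")
    code = omp_solve(y, model.dictionary, budget)
    alpha = code.to_dense()
    residuals = np.empty(len(model.class_order))
    for j, cls in enumerate(model.class_order):
        cols = model.class_blocks[cls]
        approx = model.dictionary.atoms[:, cols] @ alpha[cols] if cols.size else 0.0
        residuals[j] = np.linalg.norm(y - approx)
    label = model.class_order[int(np.argmin(residuals))]
    if return_residuals:
        return label, residuals
    return label


def srcal_fit(
    data: LabeledDataset,
    dict_width_factor: int = 2,
    schedule: LearningSchedule = LearningSchedule(),
    label_weight: float = 1.0,
) -> SRCALModel:
    """Learn the label-augmented analytic dictionary.

    Each training sample is l2-normalized and extended with ``label_weight``
    times the one-hot encoding of its label (the combined vector is not
    re-normalized, keeping label energy identical across samples).  A DCT
    dictionary of shape (m+c) x dict_width_factor*(m+c) is the K-SVD starting
    point.
    """
    if data.n_samples == 0:
        raise InputError("empty training set")
    if data.n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    if dict_width_factor < 2:
        raise ConfigurationError("dict_width_factor must be >= 2 for overcompleteness")
    m, c = data.length, data.n_classes
    augmented = np.empty((data.n_samples, m + c))
    for i in range(data.n_samples):
        augmented[i, :m] = l2_normalize(data.samples[i])
        augmented[i, m:] = label_weight * one_hot(data.labels[i], data.class_order)
    initial = make_dct_dictionary(m + c, dict_width_factor * (m + c), split_row=m)
    learned = ksvd_learn(augmented, initial, schedule)
    return SRCALModel(learned, list(data.class_order), schedule.sparse_factor)


def srcal_predict(
    model: SRCALModel,
    y,
    budget: CodingBudget | None = None,
    *,
    renormalize_upper: bool = True,
    return_label_vector: bool = False,
):
    """Code ``y`` against the signal block, read the class off the label block.

    The full dictionary columns are unit-norm but their signal-block tops are
    not; by default those are re-normalized for coding and the coefficients
    rescaled back, so the label vector ``L_y`` is computed in the original
    column scale.  Returns the class with the largest ``|L_y|`` entry
    (ties -> earlier class in class_order).
    """
    if budget is None:
        budget = CodingBudget(model.sparse_factor)
    y = l2_normalize(y)
    if y.size != model.m:
        raise InputError(f"sample length {y.size} != model dimension {model.m}")
    upper = model.learned.upper
    lower = model.learned.lower
    if renormalize_upper:
        norms = np.linalg.norm(upper, axis=0)
        usable = norms > 1e-12
        coding_atoms = np.where(usable, 1.0, 0.0) * upper / np.where(usable, norms, 1.0)
        code = omp_solve(y, coding_atoms, budget)
        alpha = code.to_dense()
        alpha[usable] /= norms[usable]
    else:
        code = omp_solve(y, upper, budget)
        alpha = code.to_dense()
    label_vector = lower @ alpha
    label = model.class_order[int(np.argmax(np.abs(label_vector)))]
    if return_label_vector:
        return label, label_vector
    return label


def save_srcal_model(model: SRCALModel, path) -> None:
    """Serialize an SRC-AL model: a JSON header line, then the atom matrix."""
    import json
    from pathlib import Path

    path = Path(path)
    header = {
        "class_order": [str(c) for c in model.class_order],
        "m": model.m,
        "c": model.n_classes,
        "sparse_factor": model.sparse_factor,
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for row in model.learned.atoms:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_srcal_model(path) -> SRCALModel:
    import json
    from pathlib import Path

    from .errors import FormatError

    path = Path(path)
    with path.open() as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: bad model header: {exc}") from None
        atoms = np.loadtxt(fh, ndmin=2)
    expected_rows = header["m"] + header["c"]
    if atoms.shape[0] != expected_rows:
        raise FormatError(f"{path}: matrix has {atoms.shape[0]} rows, header implies {expected_rows}")
    return SRCALModel(
        Dictionary(atoms, split_row=header["m"]),
        list(header["class_order"]),
        int(header["sparse_factor"]),
    )


class SRCClassifier:
    """fit/predict wrapper around :func:`src_fit`/:func:`src_predict`."""

    def __init__(self, sparse_factor: int = 5):
        self.budget = CodingBudget(sparse_factor)
        self.model: SRCModel | None = None

    def fit(self, data: LabeledDataset) -> "SRCClassifier":
        self.model = src_fit(data)
        return self

    def predict(self, y):
        if self.model is None:
            raise ConfigurationError("classifier is not fitted")
        return src_predict(self.model, y, self.budget)


class SRCALClassifier:
    """fit/predict wrapper around :func:`srcal_fit`/:func:`srcal_predict`."""

    def __init__(
        self,
        sparse_factor: int = 5,
        n_iterations: int = 30,
        dict_width_factor: int = 2,
        label_weight: float = 1.0,
    ):
        self.schedule = LearningSchedule(n_iterations=n_iterations, sparse_factor=sparse_factor)
        self.dict_width_factor = dict_width_factor
        self.label_weight = label_weight
        self.model: SRCALModel | None = None

    def fit(self, data: LabeledDataset) -> "SRCALClassifier":
        self.model = srcal_fit(
            data,
            dict_width_factor=self.dict_width_factor,
            schedule=self.schedule,
            label_weight=self.label_weight,
        )
        return self

    def predict(self, y):
        if self.model is None:
            raise ConfigurationError("classifier is not fitted")
        return srcal_predict(self.model, y)
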