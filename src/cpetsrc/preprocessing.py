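"""Turning raw breath-by-breath series into a classifier-ready dataset.

CPET indicators are sampled once per breath, so patients with different
exercise durations yield series of different lengths (85-270 breaths in the
exercise phase).  The pipeline is: linear resampling to a common length,
l2 normalization, and one-hot label encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

#: Breath-by-breath indicators recorded during CPET, in conventional order.
INDICATORS = ("HR", "SV", "CO", "VO2/HR", "VO2/kg", "VT", "VE", "R", "VE/VCO2")

PHASES = ("resting", "warmup", "exercise", "recovery")

#: Default common length per phase: the longest series observed in that phase.
DEFAULT_TARGET_LENGTH = {"warmup": 81, "exercise": 270, "recovery": 195}


@dataclass(frozen=True)
class RawSeries:
    """One variable-length univariate series with its indicator and phase tags."""

    values: np.ndarray
    indicator: str = "VO2/HR"
    phase: str = "exercise"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", values)
        if values.size < 2:
            raise InputError("a raw series needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise InputError("raw series contains non-finite values")
        if self.phase not in PHASES:
            raise InputError(f"unknown phase {self.phase!r}")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class LabeledDataset:
    """Equal-length samples with class labels.

    ``samples`` is an (n, m) array, one sample per row; ``class_order`` fixes
    the class-to-index mapping used by one-hot encoding and label vectors.
    """

    samples: np.ndarray
    labels: list
    class_order: list

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.labels = list(self.labels)
        self.class_order = list(self.class_order)
        if self.samples.shape[0] != len(self.labels):
            raise InputError(
                f"{self.samples.shape[0]} samples but {len(self.labels)} labels"
            )
        if len(self.class_order) < 2:
            raise ConfigurationError("need at least 2 classes")
        if len(set(self.class_order)) != len(self.class_order):
            raise ConfigurationError("duplicate entries in class_order")
        unknown = set(self.labels) - set(self.class_order)
        if unknown:
            raise InputError(f"labels not in class_order: {sorted(map(str, unknown))}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def length(self) -> int:
        return self.samples.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            self.samples[indices],
            [self.labels[i] for i in indices],
            self.class_order,
        )


def resample_linear(series, target_length: int) -> np.ndarray:
    """Resample to ``target_length`` points by linear interpolation.

    The original indices are mapped to [0, L-1] and the target grid is uniform
    over the same closed interval, so the first and last values are preserved
    exactly and an input already at the target length is returned unchanged.
    """
    values = series.values if isinstance(series, RawSeries) else np.asarray(series, dtype=np.float64).ravel()
    if values.size < 2:
        raise InputError("need at least 2 points to resample")
    if target_length < 2:
        raise InputError("target_length must be >= 2")
    if values.size == target_length:
        return values.copy()
    old_grid = np.arange(values.size, dtype=np.float64)
    new_grid = np.linspace(0.0, values.size - 1.0, target_length)
    return np.interp(new_grid, old_grid, values)


def l2_normalize(x) -> np.ndarray:
    """Scale ``x`` to unit l2 norm; errors on a zero vector (flat/degenerate series)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    norm = np.linalg.norm(x)
    if norm <= 0 or not np.isfinite(norm):
        raise InputError("cannot l2-normalize a zero or non-finite vector")
    return x / norm


def one_hot(label, class_order: Sequence) -> np.ndarray:
    """One-hot encoding of ``label`` against the fixed ``class_order``."""
    class_order = list(class_order)
    try:
        pos = class_order.index(label)
    except ValueError:
        raise InputError(f"label {label!r} not in class_order {class_order}") from None
    vec = np.zeros(len(class_order))
    vec[pos] = 1.0
    return vec


def build_dataset(
    raw: Sequence[RawSeries],
    labels: Sequence,
    target_length: int | None = None,
    class_order: Sequence | None = None,
) -> LabeledDataset:
    """Resample + normalize a collection of raw series into a LabeledDataset.

    All series must come from the same CPET phase (a dictionary learned on one
    phase is not transferable to another because the data dimension differs);
    ``target_length`` defaults to that phase's longest observed series.
    """
    raw = list(raw)
    labels = list(labels)
    if not raw:
        raise InputError("empty input")
    if len(raw) != len(labels):
        raise InputError(f"{len(raw)} series but {len(labels)} labels")
    phases = {s.phase for s in raw}
    if len(phases) > 1:
        raise ConfigurationError(f"mixed phases in one dataset: {sorted(phases)}")
    phase = phases.pop()
    if target_length is None:
        target_length = DEFAULT_TARGET_LENGTH.get(phase, max(len(s) for s in raw))
    if class_order is None:
        class_order = sorted(set(labels), key=str)

    samples = np.empty((len(raw), target_length))
    for i, series in enumerate(raw):
        try:
            samples[i] = l2_normalize(resample_linear(series, target_length))
        except InputError as exc:
            raise InputError(f"record {i} (label {labels[i]!r}): {exc}") from exc
    return LabeledDataset(samples, labels, list(class_order))
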