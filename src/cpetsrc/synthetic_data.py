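"""Synthetic two-class CPET-like series with controllable separability.

Emulates exercise-phase indicator curves (e.g. oxygen pulse rising under an
incremental cycling load): a saturating ramp ``a * t / (t + b)`` on normalized
time, with breath-by-breath measurement noise modeled as a stationary AR(1)
process.  "Strong responder" series follow the rising ramp throughout;
"weak responder" series plateau partway through the test and then decline —
the oxygen-pulse flattening pattern associated with limited stroke-volume
reserve.  ``effect_size`` controls how early the plateau sets in and how
steep the decline is; at zero effect the classes are exchangeable.

Series lengths vary per sample, mimicking patients with different exercise
durations, so the generated data exercises the full resample-and-normalize
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InputError
from .preprocessing import LabeledDataset, RawSeries

CLASS_STRONG = "strong"
CLASS_WEAK = "weak"

# Base saturating-ramp parameters (dimensionless indicator units).
_BASE_AMPLITUDE = 1.0
_BASE_CURVATURE = 0.3
# Weak-class shape: plateau onset at fraction 1/(1+e) of the test, then a
# decline with slope _DECLINE_RATE * e (e = effect_size).
_DECLINE_RATE = 0.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation conditions for a two-class synthetic cohort.

    Defaults mirror a small clinical CPET cohort: 12 patients per class,
    exercise-phase series of 85-270 breaths, a clearly separable class effect
    and moderate autocorrelated noise.
    """

    n_per_class: int = 12
    length_range: tuple[int, int] = (85, 270)
    effect_size: float = 1.0
    noise_sd: float = 0.1
    ar_coefficient: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if lo < 2 or hi < lo:
            raise ConfigurationError(f"invalid length_range {self.length_range}")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ConfigurationError("effect_size and noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigurationError("ar_coefficient must be in [0, 1)")


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + shocks[t - 1]
    return eps


def class_curve(t: np.ndarray, cls: str, effect_size: float) -> np.ndarray:
    """Noiseless indicator curve on normalized time ``t`` in [0, 1].

    Strong responders follow the saturating ramp ``a * t / (t + b)``.  Weak
    responders follow the same ramp up to a plateau at ``tau = 1/(1+e)`` of
    the test and decline linearly afterwards with slope ``0.8 * e`` (e =
    ``effect_size``); at e = 0 both classes coincide.  Because downstream
    samples are l2-normalized, the class signal lives entirely in the curve
    shape.
    """
    if cls == CLASS_STRONG or effect_size == 0:
        tau, decline = 1.0, 0.0
    else:
        tau = 1.0 / (1.0 + effect_size)
        decline = _DECLINE_RATE * effect_size
    tc = np.minimum(t, tau)
    ramp = _BASE_AMPLITUDE * tc / (tc + _BASE_CURVATURE)
    return ramp - decline * np.maximum(t - tau, 0.0)


def generate(spec: SyntheticSpec) -> tuple[list[RawSeries], list[str]]:
    """Generate raw series and labels, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    series: list[RawSeries] = []
    labels: list[str] = []
    for cls in (CLASS_STRONG, CLASS_WEAK):
        for _ in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            t = np.linspace(0.0, 1.0, length)
            curve = class_curve(t, cls, spec.effect_size)
            values = curve + _ar1_noise(rng, length, spec.noise_sd, spec.ar_coefficient)
            series.append(RawSeries(values, indicator="VO2/HR", phase="exercise"))
            labels.append(cls)
    return series, labels


# ---------------------------------------------------------------------------
# UCR-style flat-file I/O: one record per line, class label first, then the
# values, delimiter-separated.  Real UCR archive files are drop-in readable.

def write_ucr_style(dataset: LabeledDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write equal-length labeled samples in UCR flat format (tab by default)."""
    path = Path(path)
    with path.open("w") as fh:
        for label, row in zip(dataset.labels, dataset.samples):
            fh.write(delimiter.join([str(label)] + [f"{v:.12g}" for v in row]) + "\n")


def read_ucr_style(path: str | Path, class_order: Sequence | None = None) -> LabeledDataset:
    """Read a UCR-style file (tab or comma delimited) into a LabeledDataset."""
    path = Path(path)
    labels: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",") if ("," in line and "\t" not in line) else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need a label and at least one value")
            try:
                values = np.array([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if width is None:
                width = values.size
            elif values.size != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {values.size} values, expected {width}"
                )
            labels.append(fields[0])
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no records")
    if class_order is None:
        class_order = sorted(set(labels))
    return LabeledDataset(np.vstack(rows), labels, list(class_order))
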