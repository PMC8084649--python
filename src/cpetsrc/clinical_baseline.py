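"""Responder labeling from ambulatory BP change, and the clinical baseline.

Throughout, BP means the sum of systolic and diastolic pressure (mmHg).
Ground-truth responder labels come from 24-hour mean BP before (MBPB) and
after (MBPA) a 12-week aerobic exercise program: each patient's percent change
rate is z-standardized against the cohort and patients above the cohort mean
(z > 0) are "strong" responders, below it "weak".

The clinician's baseline predictor uses two readings from a single pre-treatment
CPET: resting BP before exercise (PEBP) and BP at the 6th minute of recovery
(R6BP).  A patient whose recovery BP undershoots the resting value
(dBP = PEBP - R6BP >= 0) is predicted to respond strongly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, FormatError, InputError

STRONG = "Strong"
WEAK = "Weak"


@dataclass(frozen=True)
class PatientBPRecord:
    """The four BP scalars per patient; unused fields may be None."""

    patient_id: int
    MBPB: float | None = None
    MBPA: float | None = None
    PEBP: float | None = None
    R6BP: float | None = None

    def __post_init__(self) -> None:
        for name in ("MBPB", "MBPA", "PEBP", "R6BP"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise InputError(f"patient {self.patient_id}: {name} must be positive")


@dataclass(frozen=True)
class ResponseLabel:
    """Change rate (percent), standardized score, and the resulting label."""

    r: float
    z: float
    label: str


def change_rate(MBPB: float, MBPA: float, mode: Literal["absolute", "signed"] = "absolute") -> float:
    """Percent BP change rate between before- and after-treatment means.

    ``absolute`` returns |MBPB - MBPA| / MBPB * 100 (the form used for
    labeling); ``signed`` returns (MBPB - MBPA) / MBPB * 100, positive for a
    BP decrease (the form whose cohort mean is conventionally reported).
    """
    if not MBPB > 0:
        raise InputError("MBPB must be positive")
    if mode == "absolute":
        return abs(MBPB - MBPA) / MBPB * 100.0
    if mode == "signed":
        return (MBPB - MBPA) / MBPB * 100.0
    raise InputError(f"unknown mode {mode!r}")


def zscore_labels(
    rates: Sequence[float],
    std_mode: Literal["population", "sample"] = "population",
) -> list[ResponseLabel]:
    """Standardize change rates against the cohort and label by the sign of z.

    z_i = (r_i - mean) / std with the population convention (divide by n) by
    default; strong responder iff z > 0.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.size < 2:
        raise InputError("need at least 2 patients")
    if not np.all(np.isfinite(rates)):
        raise InputError("rates contain non-finite values")
    ddof = 0 if std_mode == "population" else 1
    sigma = float(rates.std(ddof=ddof))
    if sigma <= 0:
        raise DegenerateCohortError("all change rates equal; labels undefined")
    z = (rates - rates.mean()) / sigma
    return [ResponseLabel(float(r), float(zi), STRONG if zi > 0 else WEAK) for r, zi in zip(rates, z)]


def baseline_predict(PEBP: float, R6BP: float) -> str:
    """Weak iff recovery BP exceeds resting BP (dBP = PEBP - R6BP < 0), else strong."""
    if not (PEBP > 0 and R6BP > 0):
        raise InputError("PEBP and R6BP must be positive")
    return WEAK if PEBP - R6BP < 0 else STRONG


def evaluate_baseline(records: Sequence[PatientBPRecord], real_labels: dict | Sequence) -> dict:
    """Run the baseline predictor on a cohort and score it against real labels.

    ``real_labels`` is either a mapping patient_id -> label or a sequence
    aligned with ``records``.  Returns predictions, the confusion matrix
    (positive class = strong) and accuracy/F1.
    """
    from .evaluation import confusion  # local import avoids a cycle

    records = list(records)
    if not records:
        raise InputError("no records")
    if isinstance(real_labels, dict):
        missing = [r.patient_id for r in records if r.patient_id not in real_labels]
        if missing:
            raise InputError(f"no real label for patient ids {missing}")
        truth = [real_labels[r.patient_id] for r in records]
    else:
        truth = list(real_labels)
        if len(truth) != len(records):
            raise InputError("real_labels length does not match records")
    for r in records:
        if r.PEBP is None or r.R6BP is None:
            raise InputError(f"patient {r.patient_id}: PEBP/R6BP required for the baseline")
    preds = [baseline_predict(r.PEBP, r.R6BP) for r in records]
    cm = confusion(preds, truth, positive_class=STRONG)
    return {
        "predictions": preds,
        "confusion": cm,
        "accuracy": cm.accuracy,
        "f1": cm.f1,
    }


def label_cohort(
    records: Sequence[PatientBPRecord],
    mode: Literal["absolute", "signed"] = "absolute",
    std_mode: Literal["population", "sample"] = "population",
) -> pd.DataFrame:
    """Full labeling pipeline: change rates, z-scores and labels for a cohort."""
    records = list(records)
    for r in records:
        if r.MBPB is None or r.MBPA is None:
            raise InputError(f"patient {r.patient_id}: MBPB/MBPA required for labeling")
    rates = [change_rate(r.MBPB, r.MBPA, mode) for r in records]
    labeled = zscore_labels(rates, std_mode=std_mode)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "MBPB": [r.MBPB for r in records],
            "MBPA": [r.MBPA for r in records],
            "r": [l.r for l in labeled],
            "z": [l.z for l in labeled],
            "label": [l.label for l in labeled],
        }
    )


# ---------------------------------------------------------------------------
# Packaged patient tables and CSV I/O

def _read_patient_csv(source) -> pd.DataFrame:
    df = pd.read_csv(source)
    if "Sample" not in df.columns:
        raise FormatError("patient table must have a 'Sample' column")
    return df


def load_labeling_table() -> pd.DataFrame:
    """Packaged 24-patient labeling table (MBPB/MBPA plus printed r, z, label)."""
    with resources.files("cpetsrc.data").joinpath("table1.csv").open() as fh:
        return _read_patient_csv(fh)


def load_baseline_table() -> pd.DataFrame:
    """Packaged 24-patient baseline table (PEBP/R6BP plus printed labels)."""
    with resources.files("cpetsrc.data").joinpath("table2.csv").open() as fh:
        return _read_patient_csv(fh)


def records_from_frame(df: pd.DataFrame) -> list[PatientBPRecord]:
    """Build records from any patient table carrying a subset of the BP columns."""
    def col(row, name):
        key = f"{name} (mmHg)"
        if key in df.columns:
            return float(row[key])
        if name in df.columns:
            return float(row[name])
        return None

    return [
        PatientBPRecord(
            patient_id=int(row["Sample"]),
            MBPB=col(row, "MBPB"),
            MBPA=col(row, "MBPA"),
            PEBP=col(row, "PEBP"),
            R6BP=col(row, "R6BP"),
        )
        for _, row in df.iterrows()
    ]


def load_patient_csv(path: str | Path) -> list[PatientBPRecord]:
    """Read a patient table CSV from disk into records."""
    return records_from_frame(_read_patient_csv(Path(path)))
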