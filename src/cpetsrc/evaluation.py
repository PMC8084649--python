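"""Leave-one-out cross-validation, sparse-factor grid search and metrics.

With a cohort of a few dozen patients, held-out test sets are not an option:
every sample is predicted once by a model trained on the remaining n-1
(the dictionary is re-learned per fold for SRC-AL).  Performance is
summarized by accuracy and the F1 score of the positive ("strong responder")
class.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .preprocessing import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with an explicit positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: object

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("precision undefined (no positive predictions); reporting 0", stacklevel=2)
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("recall undefined (no positive truths); reporting 0", stacklevel=2)
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = self.precision, self.recall
        if p + r == 0:
            warnings.warn("F1 undefined; reporting 0", stacklevel=2)
            return 0.0
        return 2 * p * r / (p + r)


def confusion(pred_labels: Sequence, true_labels: Sequence, positive_class) -> ConfusionMatrix:
    """Tally binary predictions against truths."""
    pred, true = list(pred_labels), list(true_labels)
    if not pred:
        raise InputError("empty predictions")
    if len(pred) != len(true):
        raise InputError(f"{len(pred)} predictions but {len(true)} truths")
    classes = set(pred) | set(true)
    if positive_class not in classes:
        classes.add(positive_class)
    if len(classes) > 2:
        raise InputError(f"confusion matrix is binary; saw classes {sorted(map(str, classes))}")
    tp = sum(p == t == positive_class for p, t in zip(pred, true))
    fp = sum(p == positive_class != t for p, t in zip(pred, true))
    fn = sum(t == positive_class != p for p, t in zip(pred, true))
    tn = len(pred) - tp - fp - fn
    return ConfusionMatrix(tp, fp, fn, tn, positive_class)


@dataclass
class CVReport:
    """Per-fold LOO predictions with aggregate metrics and run provenance."""

    predictions: list
    true_labels: list
    accuracy: float
    f1: float
    positive_class: object
    sparse_factor: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.predictions)

    def to_json(self, **kwargs) -> str:
        payload = dataclasses.asdict(self)
        payload["predictions"] = [str(p) for p in payload["predictions"]]
        payload["true_labels"] = [str(t) for t in payload["true_labels"]]
        payload["positive_class"] = str(payload["positive_class"])
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)


def loo_cv(
    data: LabeledDataset,
    classifier_factory: Callable[[], object],
    positive_class=None,
    config: dict | None = None,
) -> CVReport:
    """Leave-one-out cross-validation of any fit/predict classifier.

    ``classifier_factory`` returns a fresh unfitted classifier exposing
    ``fit(LabeledDataset)`` and ``predict(sample) -> label``; it is re-fit for
    every fold so any dictionary learning is repeated on the n-1 training
    samples.
    """
    if data.n_samples < 2:
        raise InputError("LOO needs at least 2 samples")
    if len(set(data.labels)) < 2:
        raise InputError("both classes must be present in the dataset")
    if positive_class is None:
        positive_class = data.class_order[0]

    predictions = []
    for i in range(data.n_samples):
        train_idx = [j for j in range(data.n_samples) if j != i]
        train = data.subset(train_idx)
        if len(set(train.labels)) < len(data.class_order):
            logger.warning("fold %d: a class is absent from the training split", i)
        clf = classifier_factory()
        clf.fit(train)
        predictions.append(clf.predict(data.samples[i]))

    cm = confusion(predictions, data.labels, positive_class)
    return CVReport(
        predictions=predictions,
        true_labels=list(data.labels),
        accuracy=cm.accuracy,
        f1=cm.f1,
        positive_class=positive_class,
        config=dict(config or {}),
    )


def grid_search_k(
    data: LabeledDataset,
    classifier_factory: Callable[[int], object],
    k_values: Sequence[int],
    positive_class=None,
) -> tuple[int, dict[int, CVReport]]:
    """LOO accuracy for each sparse factor k; best k maximizes accuracy.

    ``classifier_factory(k)`` must return a fresh classifier using sparse
    factor ``k``.  Ties go to the smallest k.  The selection uses the same
    (unnested) LOO loop whose accuracy is reported.
    """
    k_values = list(k_values)
    if not k_values:
        raise InputError("k_values is empty")
    for k in k_values:
        if k < 1 or k > data.length:
            raise ConfigurationError(f"sparse factor {k} outside [1, {data.length}]")
    reports: dict[int, CVReport] = {}
    for k in sorted(k_values):
        report = loo_cv(data, lambda: classifier_factory(k), positive_class)
        report.sparse_factor = k
        reports[k] = report
    best_k = max(sorted(reports), key=lambda k: reports[k].accuracy)
    return best_k, reports


def nested_loo_cv(
    data: LabeledDataset,
    classifier_factory: Callable[[int], object],
    k_values: Sequence[int],
    positive_class=None,
) -> CVReport:
    """Nested leave-one-out: the sparse factor is re-selected inside each fold.

    For every held-out sample, ``grid_search_k`` runs on the remaining n-1
    samples alone, the winning k trains a model on those n-1, and that model
    predicts the held-out sample.  Unbiased but quadratic in n; the unnested
    :func:`grid_search_k` is the cheaper, optimistic alternative.
    """
    if data.n_samples < 3:
        raise InputError("nested LOO needs at least 3 samples")
    if positive_class is None:
        positive_class = data.class_order[0]
    predictions = []
    chosen: list[int] = []
    for i in range(data.n_samples):
        train = data.subset([j for j in range(data.n_samples) if j != i])
        best_k, _ = grid_search_k(train, classifier_factory, k_values, positive_class)
        clf = classifier_factory(best_k)
        clf.fit(train)
        predictions.append(clf.predict(data.samples[i]))
        chosen.append(best_k)
    cm = confusion(predictions, data.labels, positive_class)
    return CVReport(
        predictions=predictions,
        true_labels=list(data.labels),
        accuracy=cm.accuracy,
        f1=cm.f1,
        positive_class=positive_class,
        config={"protocol": "nested_loo", "k_values": list(k_values), "chosen_k": chosen},
    )
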