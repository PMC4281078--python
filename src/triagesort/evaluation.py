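"""Confusion matrix and positive-class evaluation metrics.

Accuracy is deliberately absent: under a ~90/10 class imbalance a classifier
that rejects everything is ~90% accurate while useless for triage.  Instead
the package reports Precision, Recall, F-measure, F-beta (beta = 2 by
default, weighting recall over precision — a missed relevant paper costs a
curator more than a false candidate) and the Matthews Correlation
Coefficient, all computed for the positive (curatable) class.

Every 0/0 case (no positive predictions, no positive instances, a zero MCC
denominator) is defined as 0 and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .schema import POSITIVE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f_measure: float
    f_beta: float
    mcc: float
    beta: float = 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            f"f_{self.beta:g}": self.f_beta,
            "mcc": self.mcc,
        }


def confusion(
    predictions: Sequence[str],
    labels: Sequence[str],
    positive_class: str = POSITIVE,
) -> ConfusionMatrix:
    """Tally TP/FP/FN/TN of aligned prediction and gold-label sequences."""
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(labels)} labels"
        )
    tp = fp = fn = tn = 0
    for pred, gold in zip(predictions, labels):
        if pred == positive_class:
            if gold == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if gold == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("%s undefined (0/0); reported as 0", what)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, beta: float = 2.0) -> MetricsReport:
    """Precision, recall, F, F-beta and MCC for the positive class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    r = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    f = _ratio(2.0 * p * r, p + r, "f-measure")
    b2 = beta * beta
    fb = _ratio((1.0 + b2) * p * r, b2 * p + r, "f-beta")
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = _ratio(
        cm.tp * cm.tn - cm.fp * cm.fn, math.sqrt(denom) if denom else 0.0, "mcc"
    )
    return MetricsReport(
        precision=p, recall=r, f_measure=f, f_beta=fb, mcc=mcc, beta=beta
    )
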