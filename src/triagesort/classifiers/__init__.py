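"""Learners for the triage task, behind one train/predict contract.

All classifiers consume a documents x features count matrix (dense or scipy
sparse) with labels encoded 0 = negative (reject), 1 = positive (curate),
and are interchangeable in the experiment grid:

- :class:`~triagesort.classifiers.naive_bayes.NaiveBayes` — multinomial
  Naive Bayes with add-alpha smoothing, implemented from scratch.
- :class:`~triagesort.classifiers.lmt.LMTClassifier` — Logistic Model Tree
  (decision tree with LogitBoost logistic models in the leaves), implemented
  from scratch.
- :class:`~triagesort.classifiers.svm.MaxMarginClassifier` — maximum-margin
  classifier; the decision function (kernel sum over support vectors + bias)
  is evaluated here, training delegates to an established convex solver.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

MODEL_FORMAT = "triagesort-model-v1"


def as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.atleast_2d(np.asarray(X, dtype=np.float64))


class ClassifierBase:
    """Shared width bookkeeping for the train/predict contract."""

    kind: str = ""

    def __init__(self) -> None:
        self.n_features_: int | None = None

    def _start_fit(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        Xd = as_dense(X)
        y = np.asarray(y, dtype=np.int64)
        if Xd.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.n_features_ = Xd.shape[1]
        return Xd, y

    def _check_width(self, X) -> np.ndarray:
        Xd = as_dense(X)
        if self.n_features_ is None:
            raise ValueError("classifier is not fitted")
        if Xd.shape[1] != self.n_features_:
            raise ValueError(
                f"feature width mismatch: got {Xd.shape[1]}, "
                f"model was trained with {self.n_features_}"
            )
        return Xd


from .naive_bayes import NaiveBayes  # noqa: E402
from .lmt import LMTClassifier, LogitBoost  # noqa: E402
from .svm import MaxMarginClassifier  # noqa: E402

CLASSIFIER_KINDS = ("nb", "lmt", "svm")


def make_classifier(kind: str, seed: int | None = None, **params):
    """Instantiate a classifier by its short name ("nb", "lmt", "svm")."""
    if kind == "nb":
        return NaiveBayes(**params)
    if kind == "lmt":
        return LMTClassifier(seed=seed, **params)
    if kind == "svm":
        return MaxMarginClassifier(**params)
    raise ValueError(f"unknown classifier kind {kind!r}")


def save_model(model, path: str | Path) -> None:
    payload = {"format": MODEL_FORMAT, "kind": model.kind, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
    kind = payload["kind"]
    cls = {"nb": NaiveBayes, "lmt": LMTClassifier, "svm": MaxMarginClassifier}[kind]
    return cls.from_dict(payload["model"])


__all__ = [
    "ClassifierBase",
    "CLASSIFIER_KINDS",
    "LMTClassifier",
    "LogitBoost",
    "MaxMarginClassifier",
    "NaiveBayes",
    "as_dense",
    "load_model",
    "make_classifier",
    "save_model",
]
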