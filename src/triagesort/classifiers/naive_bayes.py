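"""Multinomial Naive Bayes with add-alpha smoothing, from scratch.

The model assumes feature counts are conditionally independent given the
class.  A document's score for class c is

    log P(c) + sum_f  n_f * log P(f | c)

with P(c) the class prior (class count / N) and

    P(f | c) = (count(f, c) + alpha) / (sum_f count(f, c) + alpha * |V|).

The predicted label maximizes the score; a tie goes to the negative
(majority) class.  With alpha = 0 a feature unseen in a class has zero
likelihood; its log is replaced by a large negative constant so prediction
stays defined (log-space guard).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from . import ClassifierBase

#: stands in for log(0) so that 0 * LOG_ZERO = 0 remains valid in dot products
LOG_ZERO = -1e30


class NaiveBayes(ClassifierBase):
    kind = "nb"

    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.alpha = float(alpha)
        self.log_prior_: np.ndarray | None = None  # (2,)
        self.log_likelihood_: np.ndarray | None = None  # (2, F)

    def fit(self, X, y) -> "NaiveBayes":
        Xd, y = self._start_fit(X, y)
        n = len(y)
        priors = np.array([(y == 0).sum() / n, (y == 1).sum() / n])
        self.log_prior_ = np.log(priors)

        counts = np.vstack([Xd[y == 0].sum(axis=0), Xd[y == 1].sum(axis=0)])
        smoothed = counts + self.alpha
        totals = smoothed.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            ll = np.log(smoothed) - np.log(totals)
        self.log_likelihood_ = np.where(np.isfinite(ll), ll, LOG_ZERO)
        return self

    def log_scores(self, X) -> np.ndarray:
        """Per-class unnormalized log-scores, shape (n, 2)."""
        Xd = self._check_width(X)
        return self.log_prior_ + Xd @ self.log_likelihood_.T

    def predict_log_proba(self, X) -> np.ndarray:
        s = self.log_scores(X)
        return s - logsumexp(s, axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        s = self.log_scores(X)
        # strict inequality: ties fall to the negative (majority) class
        return (s[:, 1] > s[:, 0]).astype(np.int64)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_features": self.n_features_,
            "log_prior": self.log_prior_.tolist(),
            "log_likelihood": self.log_likelihood_.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NaiveBayes":
        model = cls(alpha=data["alpha"])
        model.n_features_ = data["n_features"]
        model.log_prior_ = np.asarray(data["log_prior"])
        model.log_likelihood_ = np.asarray(data["log_likelihood"])
        return model
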