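"""Maximum-margin classifier over count vectors.

The decision function is the classical support-vector form

    y(x) = sum_i  w_i * K(x, s_i) + b

with support vectors s_i, dual weights w_i, kernel K (linear by default, RBF
selectable) and bias b; the predicted class is the sign of y(x) (positive
sign -> positive class, exact zero -> negative).  The decision value is
evaluated by this module from the stored support vectors; *training* — the
convex margin-maximization — delegates to scikit-learn's libsvm-based SVC,
an established solver for this problem.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from . import ClassifierBase


class MaxMarginClassifier(ClassifierBase):
    kind = "svm"

    def __init__(
        self, kernel: str = "linear", C: float = 1.0, gamma: str | float = "scale"
    ) -> None:
        super().__init__()
        if kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        self.kernel = kernel
        self.C = float(C)
        self.gamma = gamma
        self.support_vectors_: np.ndarray | None = None
        self.dual_weights_: np.ndarray | None = None  # y_i * alpha_i
        self.bias_: float | None = None
        self.gamma_: float | None = None

    def fit(self, X, y) -> "MaxMarginClassifier":
        Xd, y = self._start_fit(X, y)
        svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        svc.fit(Xd, y)
        self._solver_ = svc  # kept for cross-checks; not serialized
        self.support_vectors_ = np.asarray(svc.support_vectors_, dtype=np.float64)
        self.dual_weights_ = np.asarray(svc.dual_coef_, dtype=np.float64).ravel()
        self.bias_ = float(svc.intercept_[0])
        if self.kernel == "rbf":
            if self.gamma == "scale":
                var = Xd.var()
                self.gamma_ = 1.0 / (Xd.shape[1] * var) if var > 0 else 1.0
            elif self.gamma == "auto":
                self.gamma_ = 1.0 / Xd.shape[1]
            else:
                self.gamma_ = float(self.gamma)
        return self

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        sv = self.support_vectors_
        if self.kernel == "linear":
            return X @ sv.T
        sq = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma_ * sq)

    def decision_function(self, X) -> np.ndarray:
        """Kernel sum over support vectors plus bias, evaluated here."""
        Xd = self._check_width(X)
        return self._kernel_matrix(Xd) @ self.dual_weights_ + self.bias_

    def predict(self, X) -> np.ndarray:
        # sign of the decision value; exact zero falls to the negative class
        return (self.decision_function(X) > 0).astype(np.int64)

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma if isinstance(self.gamma, str) else float(self.gamma),
            "gamma_value": self.gamma_,
            "n_features": self.n_features_,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_weights": self.dual_weights_.tolist(),
            "bias": self.bias_,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaxMarginClassifier":
        model = cls(kernel=data["kernel"], C=data["C"], gamma=data["gamma"])
        model.n_features_ = data["n_features"]
        model.support_vectors_ = np.asarray(data["support_vectors"])
        model.dual_weights_ = np.asarray(data["dual_weights"])
        model.bias_ = data["bias"]
        model.gamma_ = data["gamma_value"]
        return model
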