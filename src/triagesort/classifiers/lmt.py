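"""Logistic Model Trees: LogitBoost logistic regression in the leaves.

A Logistic Model Tree is a decision tree whose leaves hold additive logistic
regression functions grown by LogitBoost.  Boosting runs first at the root;
the iteration count is chosen by five-fold cross-validation.  The node is
then split by an information-gain criterion and boosting continues at each
child *initialized from the parent's function*, so every leaf's model is the
accumulation of the stumps fitted along its root-to-leaf path.  Splitting
stops when no split clears the gain threshold, the node is smaller than
``min_node_size``, or the node is pure.

The final classifier is  f(x) = sum over leaves l of  [x in R_l] * f_l(x),
where R_l are the disjoint leaf regions (exactly one indicator is 1 for any
instance) — equivalently, route x to its unique leaf and apply that leaf's
logistic function.  Both evaluation routes are implemented.

LogitBoost here uses the classical base learner: one simple least-squares
regression on a single attribute per iteration, fitted to the weighted
working response.  Probabilities use the symmetric parameterization
p = 1 / (1 + exp(-2 F(x))).
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import ClassifierBase

# numerical guards for the working response/weights
_Z_MAX = 4.0
_W_MIN = 1e-24
_P_EPS = 1e-10

#: a fitted stump: F(x) += slope * x[:, feature] + intercept
Stump = tuple[int, float, float]


def eval_stumps(stumps: list[Stump], X: np.ndarray) -> np.ndarray:
    F = np.zeros(X.shape[0])
    for j, a, b in stumps:
        F += a * X[:, j] + b
    return F


def _proba(F: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-2.0 * np.clip(F, -250, 250)))


def _nll(F: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(_proba(F), _P_EPS, 1.0 - _P_EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


class LogitBoost:
    """Binary LogitBoost with single-attribute least-squares base learners.

    ``fit`` may continue from an existing stump list (the parent node's
    function in a model tree).  The training negative log-likelihood is
    non-increasing across iterations: a half-step that would increase it is
    halved up to three times, and boosting stops early if it still does.
    """

    def __init__(self, n_iter: int = 30) -> None:
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        self.n_iter = n_iter

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        init_stumps: list[Stump] | None = None,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> list[Stump]:
        """Run boosting; returns the full (init + new) stump list.

        When a validation set is given, ``self.val_errors_`` records the
        validation misclassification count after each iteration (padded with
        the last value if boosting stops early).  ``self.nll_path_`` records
        the training NLL after each completed iteration.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        stumps: list[Stump] = list(init_stumps or [])
        F = eval_stumps(stumps, X)
        F_val = eval_stumps(stumps, X_val) if X_val is not None else None

        nll = _nll(F, y)
        self.nll_path_: list[float] = []
        val_errors: list[int] = []

        for _ in range(self.n_iter):
            p = np.clip(_proba(F), _P_EPS, 1.0 - _P_EPS)
            w = np.maximum(p * (1.0 - p), _W_MIN)
            z = np.clip((y - p) / w, -_Z_MAX, _Z_MAX)

            j, a, b = self._best_stump(X, z, w)
            # damped half-step keeps the training loss non-increasing
            scale, accepted = 0.5, False
            for _try in range(4):
                F_new = F + scale * (a * X[:, j] + b)
                nll_new = _nll(F_new, y)
                if nll_new <= nll + 1e-12:
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                break
            F = F_new
            nll = nll_new
            stumps.append((int(j), scale * a, scale * b))
            self.nll_path_.append(nll)
            if F_val is not None:
                F_val = F_val + scale * (a * X_val[:, j] + b)
                val_errors.append(int(((F_val > 0) != (y_val > 0.5)).sum()))

        if X_val is not None:
            # pad so the caller can index by iteration number
            last = val_errors[-1] if val_errors else int(
                ((F_val > 0) != (y_val > 0.5)).sum()
            )
            val_errors += [last] * (self.n_iter - len(val_errors))
            self.val_errors_ = np.asarray(val_errors)
        return stumps

    @staticmethod
    def _best_stump(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> Stump:
        """Weighted simple linear regression on each attribute; best SSE wins."""
        sw = w.sum()
        swx = w @ X
        swxx = w @ (X * X)
        swz = float(w @ z)
        swzz = float(w @ (z * z))
        swxz = (w * z) @ X

        var = swxx - swx * swx / sw
        cov = swxz - swx * swz / sw
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var > 1e-12, cov / np.where(var > 0, var, 1.0), 0.0)
        intercept = (swz - slope * swx) / sw
        sse = (
            swzz
            - 2.0 * slope * swxz
            - 2.0 * intercept * swz
            + slope * slope * swxx
            + 2.0 * slope * intercept * swx
            + intercept * intercept * sw
        )
        j = int(np.argmin(sse))
        return j, float(slope[j]), float(intercept[j])


def select_n_iter(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int,
    folds: int = 5,
    seed: int | None = None,
) -> int:
    """Pick the LogitBoost iteration count by stratified k-fold CV.

    Returns the iteration (1-based) with the lowest misclassification count
    summed over folds; ties go to the smaller count.
    """
    folds = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    if folds < 2 or max_iter == 1:
        return max_iter
    errors = np.zeros(max_iter)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, val_idx in skf.split(X, y):
        booster = LogitBoost(n_iter=max_iter)
        booster.fit(
            X[train_idx], y[train_idx], X_val=X[val_idx], y_val=y[val_idx]
        )
        errors += booster.val_errors_
    return int(np.argmin(errors)) + 1


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "stumps")

    def __init__(self) -> None:
        self.feature: int | None = None
        self.threshold: float | None = None
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.stumps: list[Stump] | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.stumps is not None


def _entropy(n_pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy of pos/neg splits, vectorized, 0 log 0 := 0."""
    n = np.asarray(n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, n_pos / np.where(n > 0, n, 1.0), 0.0)
        h = -(
            np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
            + np.where(
                p < 1, (1 - p) * np.log2(np.where(p < 1, 1 - p, 1.0)), 0.0
            )
        )
    return h


def best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Best (feature, midpoint threshold, information gain) over all features."""
    n = len(y)
    n_pos = float(y.sum())
    h_root = float(_entropy(np.array(n_pos), np.array(n)))
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        # candidate cut between consecutive distinct values
        boundary = np.nonzero(np.diff(xs) > 0)[0]
        if boundary.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        nl = boundary + 1.0
        pl = cum_pos[boundary]
        hl = _entropy(pl, nl)
        hr = _entropy(n_pos - pl, n - nl)
        gain = h_root - (nl / n) * hl - ((n - nl) / n) * hr
        k = int(np.argmax(gain))
        g = float(gain[k])
        if best is None or g > best[2] + 1e-15:
            thr = float((xs[boundary[k]] + xs[boundary[k] + 1]) / 2.0)
            best = (j, thr, g)
    return best


class LMTClassifier(ClassifierBase):
    """Logistic Model Tree for binary triage classification.

    Parameters
    ----------
    max_iter : int
        Upper bound on LogitBoost iterations per node; the count actually
        used is chosen by cross-validation at the root.
    cv_folds : int
        Folds for the iteration-count cross-validation.
    min_node_size : int
        Nodes smaller than this are not split.
    gain_threshold : float
        Minimum information gain (bits) for a split; ``float('inf')``
        collapses the tree to a single leaf (plain LogitBoost logistic
        regression).
    max_depth : int
        Safety cap on tree depth.
    seed : int, optional
        Seeds the CV fold shuffling (the only stochastic step).
    """

    kind = "lmt"

    def __init__(
        self,
        max_iter: int = 30,
        cv_folds: int = 5,
        min_node_size: int = 15,
        gain_threshold: float = 1e-4,
        max_depth: int = 5,
        seed: int | None = None,
    ) -> None:
        super().__init__()
        self.max_iter = max_iter
        self.cv_folds = cv_folds
        self.min_node_size = min_node_size
        self.gain_threshold = gain_threshold
        self.max_depth = max_depth
        self.seed = seed
        self.root_: _Node | None = None
        self.n_iter_: int | None = None

    def fit(self, X, y) -> "LMTClassifier":
        Xd, y = self._start_fit(X, y)
        self.n_iter_ = select_n_iter(
            Xd, y, self.max_iter, self.cv_folds, self.seed
        )
        self.root_ = self._build(Xd, y, [], depth=0)
        return self

    def _build(
        self, X: np.ndarray, y: np.ndarray, stumps: list[Stump], depth: int
    ) -> _Node:
        node = _Node()
        stumps = LogitBoost(n_iter=self.n_iter_).fit(X, y, init_stumps=stumps)

        pure = len(np.unique(y)) < 2
        if (
            pure
            or depth >= self.max_depth
            or len(y) < self.min_node_size
            or np.isinf(self.gain_threshold)
        ):
            node.stumps = stumps
            return node
        split = best_split(X, y)
        if split is None or split[2] <= self.gain_threshold:
            node.stumps = stumps
            return node
        j, thr, _gain = split
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._build(X[mask], y[mask], stumps, depth + 1)
        node.right = self._build(X[~mask], y[~mask], stumps, depth + 1)
        return node

    # -- prediction -------------------------------------------------------

    def _route(self, x: np.ndarray) -> _Node:
        node = self.root_
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability via tree routing."""
        Xd = self._check_width(X)
        out = np.empty(Xd.shape[0])
        for i, x in enumerate(Xd):
            leaf = self._route(x)
            out[i] = _proba(eval_stumps(leaf.stumps, x[None, :]))[0]
        return out

    def leaves(self) -> list[tuple[list[tuple[int, float, bool]], list[Stump]]]:
        """All (path conditions, leaf stumps); conditions are
        (feature, threshold, go_left)."""
        out: list[tuple[list[tuple[int, float, bool]], list[Stump]]] = []

        def walk(node: _Node, path: list[tuple[int, float, bool]]) -> None:
            if node.is_leaf:
                out.append((path, node.stumps))
                return
            walk(node.left, path + [(node.feature, node.threshold, True)])
            walk(node.right, path + [(node.feature, node.threshold, False)])

        walk(self.root_, [])
        return out

    def leaf_indicators(self, X) -> np.ndarray:
        """Indicator matrix (n, n_leaves): instance-in-leaf-region membership."""
        Xd = self._check_width(X)
        cols = []
        for path, _stumps in self.leaves():
            ind = np.ones(Xd.shape[0], dtype=bool)
            for j, thr, go_left in path:
                side = Xd[:, j] <= thr
                ind &= side if go_left else ~side
            cols.append(ind)
        return np.column_stack(cols)

    def predict_proba_indicator(self, X) -> np.ndarray:
        """Positive-class probability via the sum-over-leaves formulation."""
        Xd = self._check_width(X)
        ind = self.leaf_indicators(Xd).astype(float)
        leaf_p = np.column_stack(
            [_proba(eval_stumps(stumps, Xd)) for _path, stumps in self.leaves()]
        )
        return (ind * leaf_p).sum(axis=1)

    def predict(self, X) -> np.ndarray:
        # p == 0.5 falls to the negative class
        return (self.predict_proba(X) > 0.5).astype(np.int64)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def encode(node: _Node) -> dict:
            if node.is_leaf:
                return {"stumps": [[j, a, b] for j, a, b in node.stumps]}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return {
            "params": {
                "max_iter": self.max_iter,
                "cv_folds": self.cv_folds,
                "min_node_size": self.min_node_size,
                "gain_threshold": self.gain_threshold,
                "max_depth": self.max_depth,
                "seed": self.seed,
            },
            "n_features": self.n_features_,
            "n_iter": self.n_iter_,
            "tree": encode(self.root_),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LMTClassifier":
        model = cls(**data["params"])
        model.n_features_ = data["n_features"]
        model.n_iter_ = data["n_iter"]

        def decode(d: dict) -> _Node:
            node = _Node()
            if "stumps" in d:
                node.stumps = [(int(j), float(a), float(b)) for j, a, b in d["stumps"]]
            else:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = decode(d["left"])
                node.right = decode(d["right"])
            return node

        model.root_ = decode(data["tree"])
        return model
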