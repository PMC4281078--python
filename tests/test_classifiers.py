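"""The three learners: Naive Bayes, LMT/LogitBoost, max-margin classifier."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from triagesort.classifiers import (
    LMTClassifier,
    LogitBoost,
    MaxMarginClassifier,
    NaiveBayes,
    load_model,
    make_classifier,
    save_model,
)
from triagesort.evaluation import ConfusionMatrix, confusion, metrics

# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

TOY_X = np.array(
    [[2, 1, 0], [1, 0, 1], [0, 2, 3], [0, 1, 1]], dtype=float
)
TOY_Y = np.array([1, 1, 0, 0])


def nb_oracle_log_scores(X, y, x_new, alpha=1.0):
    """Exhaustive pure-python evaluation of the prior/likelihood formulas."""
    n, F = X.shape
    scores = []
    for c in (0, 1):
        rows = [i for i in range(n) if y[i] == c]
        prior = len(rows) / n
        class_counts = [sum(X[i][f] for i in rows) for f in range(F)]
        total = sum(class_counts)
        s = math.log(prior)
        for f in range(F):
            p = (class_counts[f] + alpha) / (total + alpha * F)
            s += x_new[f] * math.log(p)
        scores.append(s)
    return scores


class TestNaiveBayes:
    def test_symmetric_priors(self):
        model = NaiveBayes().fit(TOY_X, TOY_Y)
        assert np.exp(model.log_prior_) == pytest.approx([0.5, 0.5])

    def test_likelihoods_sum_to_one(self):
        model = NaiveBayes().fit(TOY_X, TOY_Y)
        sums = np.exp(model.log_likelihood_).sum(axis=1)
        assert sums == pytest.approx([1.0, 1.0], abs=1e-12)

    @pytest.mark.parametrize(
        "x_new", [[1, 0, 0], [0, 0, 2], [3, 1, 1], [0, 0, 0]]
    )
    def test_toy_scores_match_hand_oracle(self, x_new):
        model = NaiveBayes(alpha=1.0).fit(TOY_X, TOY_Y)
        got = model.log_scores(np.array([x_new], dtype=float))[0]
        want = nb_oracle_log_scores(TOY_X, TOY_Y, x_new)
        assert got == pytest.approx(want, abs=1e-12)

    def test_posterior_normalized(self):
        model = NaiveBayes().fit(TOY_X, TOY_Y)
        logp = model.predict_log_proba(TOY_X)
        assert np.exp(logp).sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)

    def test_all_zero_vector_follows_prior(self):
        X = np.eye(2)
        model = NaiveBayes().fit(
            np.vstack([X] * 3), np.array([0, 0, 0, 1, 1, 0])
        )
        assert model.predict(np.zeros((1, 2)))[0] == 0
        model = NaiveBayes().fit(
            np.vstack([X] * 3), np.array([1, 1, 1, 0, 1, 0])
        )
        assert model.predict(np.zeros((1, 2)))[0] == 1

    def test_symmetric_tie_breaks_negative(self):
        model = NaiveBayes().fit(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1])
        assert model.predict(np.array([[1.0, 1.0]]))[0] == 0

    def test_alpha_zero_guard(self):
        # feature 0 never occurs in class 0: zero likelihood, finite scores
        model = NaiveBayes(alpha=0.0).fit(TOY_X, TOY_Y)
        scores = model.log_scores(np.array([[1.0, 0, 0]]))
        assert np.all(np.isfinite(scores))
        assert model.predict(np.array([[1.0, 0, 0]]))[0] == 1

    def test_single_class_training_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            NaiveBayes().fit(TOY_X, np.zeros(4, dtype=int))

    def test_width_mismatch_is_error(self):
        model = NaiveBayes().fit(TOY_X, TOY_Y)
        with pytest.raises(ValueError, match="width"):
            model.predict(np.zeros((1, 5)))

    def test_sparse_input_equivalent(self):
        model_d = NaiveBayes().fit(TOY_X, TOY_Y)
        model_s = NaiveBayes().fit(sp.csr_matrix(TOY_X), TOY_Y)
        assert np.allclose(model_d.log_likelihood_, model_s.log_likelihood_)

    def test_save_load_round_trip(self, tmp_path):
        model = NaiveBayes().fit(TOY_X, TOY_Y)
        save_model(model, tmp_path / "nb.json")
        again = load_model(tmp_path / "nb.json")
        assert np.array_equal(again.predict(TOY_X), model.predict(TOY_X))


# ---------------------------------------------------------------------------
# LogitBoost / LMT
# ---------------------------------------------------------------------------

def separable_data(n=60, seed=0):
    """Two count features; positives high on feature 0, negatives on 1."""
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.integers(4, 9, n // 2), rng.integers(0, 2, n // 2)])
    neg = np.column_stack([rng.integers(0, 2, n // 2), rng.integers(4, 9, n // 2)])
    X = np.vstack([pos, neg]).astype(float)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestLogitBoost:
    def test_training_loss_monotone_nonincreasing(self):
        X, y = separable_data()
        booster = LogitBoost(n_iter=25)
        booster.fit(X, y)
        path = booster.nll_path_
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_continues_from_init_stumps(self):
        X, y = separable_data()
        first = LogitBoost(n_iter=5).fit(X, y)
        both = LogitBoost(n_iter=5).fit(X, y, init_stumps=first)
        assert both[: len(first)] == first
        assert len(both) > len(first)


class TestLMT:
    def test_single_leaf_reduces_to_logitboost(self):
        """With an infinite gain threshold the tree is one leaf whose
        function is exactly the plain LogitBoost logistic regression."""
        X, y = separable_data()
        lmt = LMTClassifier(max_iter=10, gain_threshold=float("inf"), seed=0)
        lmt.fit(X, y)
        assert len(lmt.leaves()) == 1
        booster_stumps = LogitBoost(n_iter=lmt.n_iter_).fit(X, y)
        assert lmt.leaves()[0][1] == booster_stumps

    def test_separable_training_accuracy_is_one(self):
        X, y = separable_data(n=80, seed=1)
        lmt = LMTClassifier(max_iter=15, seed=1).fit(X, y)
        assert np.array_equal(lmt.predict(X), y)

    def test_leaf_indicator_partition(self):
        """Every instance falls in exactly one leaf region."""
        X, y = separable_data(n=100, seed=2)
        lmt = LMTClassifier(max_iter=8, min_node_size=10, seed=2).fit(X, y)
        rng = np.random.default_rng(3)
        probe = rng.integers(0, 10, size=(1000, 2)).astype(float)
        ind = lmt.leaf_indicators(probe)
        assert np.array_equal(ind.sum(axis=1), np.ones(1000))

    def test_sum_over_leaves_equals_routing(self):
        X, y = separable_data(n=100, seed=4)
        lmt = LMTClassifier(max_iter=8, min_node_size=10, seed=4).fit(X, y)
        probe = np.random.default_rng(5).integers(0, 10, (200, 2)).astype(float)
        assert np.allclose(
            lmt.predict_proba(probe), lmt.predict_proba_indicator(probe)
        )

    def test_probability_in_unit_interval(self):
        X, y = separable_data(n=60, seed=6)
        lmt = LMTClassifier(max_iter=10, seed=6).fit(X, y)
        probe = np.random.default_rng(7).integers(0, 30, (300, 2)).astype(float)
        p = lmt.predict_proba(probe)
        assert np.all((0.0 <= p) & (p <= 1.0))

    def test_nearly_pure_nodes_become_leaves(self):
        # one stray negative among positives: any pure split child must stop
        X = np.column_stack([np.arange(20.0), np.zeros(20)])
        y = np.array([0] * 10 + [1] * 10)
        lmt = LMTClassifier(max_iter=5, min_node_size=4, seed=0).fit(X, y)
        assert np.array_equal(lmt.predict(X), y)

    def test_deterministic_given_seed(self):
        X, y = separable_data(n=60, seed=8)
        a = LMTClassifier(max_iter=10, seed=42).fit(X, y).predict_proba(X)
        b = LMTClassifier(max_iter=10, seed=42).fit(X, y).predict_proba(X)
        assert np.array_equal(a, b)

    def test_width_mismatch_is_error(self):
        X, y = separable_data()
        lmt = LMTClassifier(max_iter=5, seed=0).fit(X, y)
        with pytest.raises(ValueError, match="width"):
            lmt.predict(np.zeros((1, 7)))

    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_data(n=60, seed=9)
        lmt = LMTClassifier(max_iter=8, seed=9).fit(X, y)
        save_model(lmt, tmp_path / "lmt.json")
        again = load_model(tmp_path / "lmt.json")
        assert np.allclose(again.predict_proba(X), lmt.predict_proba(X))


# ---------------------------------------------------------------------------
# Max-margin classifier
# ---------------------------------------------------------------------------

class TestMaxMargin:
    def test_two_point_geometry(self):
        X = np.array([[0.0, 0.0], [4.0, 4.0]])
        y = np.array([0, 1])
        model = MaxMarginClassifier().fit(X, y)
        assert np.array_equal(model.predict(X), y)
        # the margin midpoint lies on the decision boundary
        assert model.decision_function(np.array([[2.0, 2.0]]))[0] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_support_vector_sign_on_separable_data(self):
        X, y = separable_data(n=40, seed=10)
        model = MaxMarginClassifier().fit(X, y)
        vals = model.decision_function(model.support_vectors_)
        preds = (vals > 0).astype(int)
        sv_labels = model._solver_.predict(model.support_vectors_)
        assert np.array_equal(preds, sv_labels)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_agreement_with_reference_solver(self, kernel):
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(0, 1, (25, 4)) + 2, rng.normal(0, 1, (25, 4)) - 2]
        )
        y = np.array([1] * 25 + [0] * 25)
        model = MaxMarginClassifier(kernel=kernel).fit(X, y)
        assert np.allclose(
            model.decision_function(X), model._solver_.decision_function(X)
        )
        assert np.array_equal(model.predict(X), model._solver_.predict(X))

    def test_single_class_training_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            MaxMarginClassifier().fit(np.eye(3), np.zeros(3, dtype=int))

    def test_width_mismatch_is_error(self):
        X, y = separable_data()
        model = MaxMarginClassifier().fit(X, y)
        with pytest.raises(ValueError, match="width"):
            model.predict(np.zeros((1, 3)))

    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_data(n=40, seed=12)
        model = MaxMarginClassifier(kernel="rbf").fit(X, y)
        save_model(model, tmp_path / "svm.json")
        again = load_model(tmp_path / "svm.json")
        assert np.allclose(
            again.decision_function(X), model.decision_function(X)
        )


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["nb", "lmt", "svm"])
def test_permuted_labels_give_near_zero_mcc(kind):
    """Destroying the label-feature association leaves no recoverable
    signal: held-out MCC stays near zero for every learner."""
    rng = np.random.default_rng(20)
    n = 1000
    X = rng.poisson(1.0, size=(n, 12)).astype(float)
    X[:, 0] += rng.integers(0, 3, n)  # mild structure, label-independent
    y = rng.integers(0, 2, n)
    X_train, y_train = X[:500], rng.permutation(y[:500])
    X_test, y_test = X[500:], y[500:]
    params = {"lmt": {"max_iter": 5}}.get(kind, {})
    model = make_classifier(kind, seed=0, **params).fit(X_train, y_train)
    pred = model.predict(X_test)
    cm = confusion(
        ["positive" if v else "negative" for v in pred],
        ["positive" if v else "negative" for v in y_test],
    )
    assert abs(metrics(cm).mcc) < 0.15


@pytest.mark.parametrize("kind", ["nb", "lmt", "svm"])
def test_interchangeable_contract(kind):
    X, y = separable_data(n=40, seed=13)
    model = make_classifier(kind, seed=0, **({"max_iter": 5} if kind == "lmt" else {}))
    pred = model.fit(sp.csr_matrix(X), y).predict(X)
    assert set(np.unique(pred)) <= {0, 1}
    assert pred.shape == (40,)
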