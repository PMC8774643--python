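import itertools

import numpy as np
import pytest
from sklearn.base import BaseEstimator
from sklearn.metrics import balanced_accuracy_score

from neuromark.rfecv import (
    ConfusionCounts,
    RFECVSelector,
    balanced_accuracy,
    importance_rank,
    make_backend,
    rfe_elimination_path,
    rfecv_select,
)


class FixedImportanceStub(BaseEstimator):
    """Backend whose importances are read off the (constant) data columns.

    Each column of X is constant and equal to that feature's importance, so
    the stub survives column elimination without external bookkeeping.
    """

    def fit(self, X, y):
        self.coef_ = np.asarray(X).mean(axis=0, keepdims=True)
        self.majority_ = int(np.asarray(y).mean() >= 0.5)
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_)


def brute_force_confusions(pos_max=6, neg_max=6):
    for pos, neg in itertools.product(range(1, pos_max + 1), range(1, neg_max + 1)):
        for tp, tn in itertools.product(range(pos + 1), range(neg + 1)):
            yield tp, tn, pos, neg


def test_balanced_accuracy_matches_enumeration_oracle():
    """Eq-style definition agrees with an exhaustive label-vector oracle."""
    for tp, tn, pos, neg in brute_force_confusions():
        got = balanced_accuracy(ConfusionCounts(tp, tn, pos, neg))
        y_true = np.array([1] * pos + [0] * neg)
        y_pred = np.array([1] * tp + [0] * (pos - tp) + [0] * tn + [1] * (neg - tn))
        want = balanced_accuracy_score(y_true, y_pred)
        assert got == pytest.approx(want, abs=1e-12)
        assert 0.0 <= got <= 1.0


def test_balanced_accuracy_worked_examples_and_symmetry():
    assert balanced_accuracy(ConfusionCounts(10, 10, 10, 10)) == 1.0
    assert balanced_accuracy(ConfusionCounts(5, 5, 10, 10)) == 0.5
    assert balanced_accuracy(ConfusionCounts(8, 3, 10, 5)) == pytest.approx(0.7)
    # symmetric under swapping the positive and negative bookkeeping
    assert balanced_accuracy(ConfusionCounts(8, 3, 10, 5)) == balanced_accuracy(
        ConfusionCounts(3, 8, 5, 10)
    )


def test_balanced_accuracy_undefined_without_both_classes():
    with pytest.raises(ValueError):
        balanced_accuracy(ConfusionCounts(0, 3, 0, 5))
    with pytest.raises(ValueError):
        ConfusionCounts(5, 3, 4, 5)  # TP > Pos is inconsistent


def test_importance_rank_minimum_and_ties():
    stub = FixedImportanceStub().fit(np.tile([3.0, 1.0, 2.0], (4, 1)), [0, 1, 0, 1])
    assert importance_rank(stub) == 1
    stub2 = FixedImportanceStub().fit(np.ones((4, 3)), [0, 1, 0, 1])
    assert importance_rank(stub2) == 0  # ties -> lowest column index
    with pytest.raises(ValueError):
        importance_rank(FixedImportanceStub())


def test_elimination_order_is_ascending_importance_under_stub():
    imps = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
    X = np.tile(imps, (12, 1))
    y = np.array([0, 1] * 6)
    rows = np.arange(12)
    scores, order = rfe_elimination_path(X, y, FixedImportanceStub(), rows, rows)
    # removed in ascending importance; the most important survives unremoved
    assert order == [1, 3, 4, 2]
    assert len(scores) == 5 and not np.isnan(scores).any()
    assert ((scores >= 0) & (scores <= 1)).all()


def test_elimination_bookkeeping_partition(matrix_factory):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 10))
    y = (X[:, 0] + rng.normal(0, 0.5, 40) > 0).astype(int)
    rows = np.arange(40)
    _, order = rfe_elimination_path(X, y, "lg2", rows, rows)
    survivor = set(range(10)) - set(order)
    assert len(order) == 9 and len(survivor) == 1
    assert sorted(order + list(survivor)) == list(range(10))


def test_single_feature_input_gives_single_score_empty_order():
    X = np.random.default_rng(1).normal(size=(20, 1))
    y = np.array([0, 1] * 10)
    rows = np.arange(20)
    scores, order = rfe_elimination_path(X, y, "lg2", rows, rows)
    assert order == [] and scores.shape == (1,)


def test_single_class_training_fold_is_hard_error():
    X = np.random.default_rng(2).normal(size=(10, 3))
    y = np.zeros(10, dtype=int)
    with pytest.raises(ValueError, match="single class"):
        rfe_elimination_path(X, y, "lg2", np.arange(10), None)


def test_rfecv_single_column_and_determinism(matrix_factory):
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 1))
    y = np.array([0, 1] * 15)
    mat = matrix_factory(X, y)
    res = rfecv_select(mat, "lg2", n_folds=5, seed=0)
    assert res.n_features == 1 and res.selected == mat.columns
    X2 = rng.normal(size=(40, 6))
    y2 = (X2[:, 2] > 0).astype(int)
    mat2 = matrix_factory(X2, y2)
    a = rfecv_select(mat2, "lg2", n_folds=5, seed=7)
    b = rfecv_select(mat2, "lg2", n_folds=5, seed=7)
    assert a.selected == b.selected and a.n_features == b.n_features
    np.testing.assert_array_equal(a.mean_scores, b.mean_scores)


def test_rfecv_keeps_perfectly_separating_feature(matrix_factory):
    rng = np.random.default_rng(12)
    n = 100
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 21))
    X[:, 13] = y * 2.0 - 1.0 + rng.normal(0, 0.05, n)  # clean separator
    mat = matrix_factory(X, y)
    res = rfecv_select(mat, "lg2", n_folds=10, seed=0)
    assert mat.columns[13] in res.selected
    assert res.n_features <= 10


def test_rfecv_with_constant_importances_selects_top_nf(matrix_factory):
    imps = np.array([0.5, 3.0, 1.0, 2.5, 2.0, 0.1])
    X = np.tile(imps, (24, 1))
    y = np.array([0, 1] * 12)
    mat = matrix_factory(X, y)
    res = rfecv_select(mat, FixedImportanceStub(), n_folds=4, seed=0)
    top = np.argsort(imps)[::-1][: res.n_features]
    assert set(res.selected) == {mat.columns[int(j)] for j in top}


def test_rfecv_rejects_tiny_cohorts(matrix_factory):
    mat = matrix_factory(np.ones((3, 4)), [0, 1, 0])
    with pytest.raises(ValueError):
        rfecv_select(mat, "lg2")


def test_rfecv_reduces_folds_for_small_classes(matrix_factory, caplog):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 4))
    y = np.array([1] * 4 + [0] * 8)
    mat = matrix_factory(X, y)
    res = rfecv_select(mat, "lg2", n_folds=10, seed=0)
    assert res.n_folds == 4


def test_selector_estimator_facade(matrix_factory):
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 8))
    y = (X[:, 3] > 0).astype(int)
    sel = RFECVSelector(backend="lg2", n_folds=5, random_state=1).fit(X, y)
    assert sel.support_.sum() == sel.n_features_
    reduced = sel.transform(X)
    assert reduced.shape == (60, sel.n_features_)
    assert sel.get_params()["backend"] == "lg2"


@pytest.mark.parametrize("backend", ["lg1", "lg2", "lsvm", "rf"])
def test_all_backends_expose_importances(backend):
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 5))
    y = (X[:, 0] > 0).astype(int)
    model = make_backend(backend, seed=0).fit(X, y)
    from neuromark.rfecv import backend_importances

    imp = backend_importances(model)
    assert imp.shape == (5,) and (imp >= 0).all()
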