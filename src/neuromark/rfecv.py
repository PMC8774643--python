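"""Recursive feature elimination with cross-validation (RFECV).

For each stratified fold, a backend classifier is fitted on the training
rows, scored on the validation rows by balanced accuracy, and its least
important feature is removed; the fit/score/remove cycle repeats until a
single feature remains, recording a validation score at every feature
count p, p-1, ..., 1.  Scores are averaged over folds per feature count;
the optimum count Nf is the argmax (ties broken toward fewer features).
A final elimination pass over *all* rows, stopped at Nf surviving
features, yields the selected set -- the neuro-atlas for that scope.

Four importance backends are supported: L1- and L2-penalized logistic
regression (``lg1``/``lg2``), a linear SVM (``lsvm``) -- importance is the
absolute coefficient -- and a random forest (``rf``) with impurity-based
importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cohort import DataMatrix
from .registry import FeatureColumn

logger = logging.getLogger(__name__)

BACKEND_IDS = ("lg1", "lg2", "lsvm", "rf")

#: fixed regularization / size defaults used during elimination (no nested
#: tuning inside the elimination loop)
_BACKEND_DEFAULTS = {
    "lg1": dict(C=1.0, max_iter=2000),
    "lg2": dict(C=1.0, max_iter=2000),
    "lsvm": dict(C=1.0, max_iter=5000),
    "rf": dict(n_estimators=50),
}


@dataclass
class ConfusionCounts:
    """TP/TN against the class totals Pos (ASD) and Neg (TD)."""

    tp: int
    tn: int
    pos: int
    neg: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.pos, self.neg) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp > self.pos or self.tn > self.neg:
            raise ValueError("TP <= Pos and TN <= Neg must hold")


@dataclass
class RfecvResult:
    """Outcome of one RFECV run for one backend on one scope."""

    backend: str
    mean_scores: np.ndarray  # index i -> mean CV score with i+1 features
    n_features: int          # Nf, the optimum feature count
    selected: list[FeatureColumn]
    seed: int
    n_folds: int


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """(TP/Pos + TN/Neg) / 2 -- the chance level is 0.5 at any imbalance."""
    if counts.pos == 0 or counts.neg == 0:
        raise ValueError("balanced accuracy is undefined when Pos or Neg is 0")
    return 0.5 * (counts.tp / counts.pos + counts.tn / counts.neg)


def balanced_accuracy_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Balanced accuracy from binary label vectors (1 = ASD positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = int((y_true == 1).sum())
    neg = int((y_true == 0).sum())
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return balanced_accuracy(ConfusionCounts(tp=tp, tn=tn, pos=pos, neg=neg))


def make_backend(backend_id, seed: int = 0) -> BaseEstimator:
    """Instantiate an importance backend with its fixed defaults.

    ``backend_id`` may also be an (unfitted) estimator instance, which is
    used as the prototype directly -- handy for stub backends in tests.
    """
    if not isinstance(backend_id, str):
        return clone(backend_id)
    if backend_id == "lg1":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", random_state=seed,
            **_BACKEND_DEFAULTS["lg1"],
        )
    if backend_id == "lg2":
        return LogisticRegression(
            l1_ratio=0.0, solver="lbfgs", **_BACKEND_DEFAULTS["lg2"],
        )
    if backend_id == "lsvm":
        return LinearSVC(random_state=seed, **_BACKEND_DEFAULTS["lsvm"])
    if backend_id == "rf":
        return RandomForestClassifier(random_state=seed, **_BACKEND_DEFAULTS["rf"])
    raise ValueError(f"unknown backend {backend_id!r}; expected one of {BACKEND_IDS}")


def backend_importances(model: BaseEstimator) -> np.ndarray:
    """Non-negative per-feature importances of a fitted backend."""
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_)).ravel()
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_)
    raise ValueError("backend is not fitted or exposes no importances")


def importance_rank(model: BaseEstimator) -> int:
    """Index of the least important feature; ties go to the lowest index."""
    imp = backend_importances(model)
    return int(np.argmin(imp))


def rfe_elimination_path(
    X: np.ndarray,
    y: np.ndarray,
    backend_id: str,
    train_rows: np.ndarray,
    val_rows: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """One full elimination pass.

    Fits on ``train_rows``; if ``val_rows`` is given, records a validation
    balanced accuracy at every feature count p..1 (otherwise scores are
    NaN).  Returns ``(scores, order)`` where ``scores[i]`` is the score
    with i+1 features remaining and ``order`` lists the column indices
    removed, in removal order (the final survivor is never removed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if p == 0:
        raise ValueError("elimination requires at least one feature")
    y_train = y[train_rows]
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            f"training rows contain a single class (fold seed {seed}); "
            "cannot run elimination"
        )
    remaining = list(range(p))
    scores = np.full(p, np.nan)
    order: list[int] = []
    proto = make_backend(backend_id, seed)
    while remaining:
        model = clone(proto)
        model.fit(X[np.ix_(train_rows, remaining)], y_train)
        if val_rows is not None:
            pred = model.predict(X[np.ix_(val_rows, remaining)])
            scores[len(remaining) - 1] = balanced_accuracy_labels(y[val_rows], pred)
        if len(remaining) == 1:
            break
        worst_local = importance_rank(model)
        order.append(remaining.pop(worst_local))
    return scores, order


def rfecv_select(
    matrix: DataMatrix,
    backend_id: str,
    n_folds: int = 10,
    seed: int = 0,
) -> RfecvResult:
    """Full RFECV: per-fold elimination paths, fold-averaged score curve,
    optimum count Nf, and a final all-rows elimination stopped at Nf."""
    X, y = matrix.values, matrix.y
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects for cross-validation, got {n}")
    class_min = int(np.bincount(y).min()) if len(np.unique(y)) == 2 else 0
    if class_min < 2:
        raise ValueError("both classes need at least 2 members")
    k = n_folds
    if class_min < k:
        logger.warning(
            "scope %s: smallest class has %d members; reducing folds %d -> %d",
            matrix.scope, class_min, k, class_min,
        )
        k = class_min
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    p = X.shape[1]
    fold_scores = np.zeros((k, p))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        scores, _ = rfe_elimination_path(X, y, backend_id, tr, va, seed=seed)
        fold_scores[f] = scores
    mean_scores = fold_scores.mean(axis=0)
    # argmax with ties broken toward the smallest feature count
    n_features = int(np.argmax(mean_scores)) + 1
    all_rows = np.arange(n)
    _, order = rfe_elimination_path(X, y, backend_id, all_rows, None, seed=seed)
    survivors = sorted(set(range(p)) - set(order[: p - n_features]))
    selected = [matrix.columns[j] for j in survivors]
    return RfecvResult(
        backend=backend_id if isinstance(backend_id, str) else type(backend_id).__name__,
        mean_scores=mean_scores,
        n_features=n_features,
        selected=selected,
        seed=seed,
        n_folds=k,
    )


class RFECVSelector(BaseEstimator):
    """Estimator facade over :func:`rfecv_select`.

    Parameters
    ----------
    backend : str
        One of ``lg1``, ``lg2``, ``lsvm``, ``rf``.
    n_folds : int
        Cross-validation folds (reduced with a warning when the smallest
        class is smaller).
    random_state : int
        Fold shuffling and backend seed.

    Attributes
    ----------
    support_ : boolean mask of selected columns
    n_features_ : the optimum feature count Nf
    cv_scores_ : mean CV balanced accuracy per feature count (index i ->
        i+1 features)
    selected_columns_ : the selected :class:`FeatureColumn` objects when a
        :class:`DataMatrix` was fitted
    """

    def __init__(self, backend: str = "lg2", n_folds: int = 10, random_state: int = 0):
        self.backend = backend
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y=None) -> "RFECVSelector":
        if isinstance(X, DataMatrix):
            matrix = X
        else:
            X = np.asarray(X, dtype=float)
            from .registry import canonical_columns

            cols = canonical_columns()[: X.shape[1]]
            matrix = DataMatrix(
                scope="global",
                columns=cols,
                values=X,
                labels=np.where(np.asarray(y) == 1, "ASD", "TD").astype(object),
                subject_ids=[f"s{i}" for i in range(X.shape[0])],
                sites=["-"] * X.shape[0],
                ages=np.full(X.shape[0], 10.0),
                sexes=["M"] * X.shape[0],
            )
        res = rfecv_select(matrix, self.backend, self.n_folds, self.random_state)
        self.result_ = res
        self.n_features_ = res.n_features
        self.cv_scores_ = res.mean_scores
        self.selected_columns_ = res.selected
        sel = {c for c in res.selected}
        self.support_ = np.array([c in sel for c in matrix.columns])
        return self

    def transform(self, X):
        if isinstance(X, DataMatrix):
            return X.restrict(self.selected_columns_)
        return np.asarray(X, dtype=float)[:, self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
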