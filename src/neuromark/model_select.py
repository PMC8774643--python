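"""Hyper-parameter grid search over eight classifier families.

The atlas-reduced matrix is scored by stratified 5-fold cross-validated
balanced accuracy for every (family, grid-point) combination; the best
mean wins.  Families: three linear (logistic regression, linear SVM,
passive-aggressive) and five non-linear (random forest, RBF-kernel SVM,
gradient-boosted trees, Gaussian naive Bayes, and a shallow/deep
neural network with tanh activation, SGD with adaptive learning rate and
an L2 penalty of 1e-4 -- depth is a grid axis of the single NN family).

Grid ranges are documented package defaults; ties are broken toward the
grid point with fewer hyper-parameters, then the earlier family in the
canonical order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from xgboost import XGBClassifier

from .cohort import DataMatrix
from .harmonize import MinMaxNormalizer
from .rfecv import balanced_accuracy_labels

FAMILY_ORDER = (
    "logistic",
    "linear_svm",
    "passive_aggressive",
    "random_forest",
    "rbf_svm",
    "gradient_boosted_trees",
    "gaussian_nb",
    "neural_net",
)


@dataclass
class ClassifierSpec:
    """One classifier family plus its hyper-parameter grid.

    ``factory(params, seed)`` overrides the built-in constructor for this
    family; used to inject stub classifiers in harness tests.
    """

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    factory: object = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.grid:
            raise ValueError("grid must be non-empty (use a single point)")

    def build(self, params: dict, seed: int):
        if self.factory is not None:
            return self.factory(params, seed)
        return build_classifier(self.family, params, seed)

    def points(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class ModelReport:
    """CV outcome of the best grid point of one family."""

    family: str
    params: dict
    fold_scores: list[float]
    seed: int
    atlas_scope: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores))


def default_classifier_specs() -> list[ClassifierSpec]:
    """The packaged default grids (documented constants)."""
    return [
        ClassifierSpec("logistic", {"C": [0.01, 0.1, 1.0, 10.0]}),
        ClassifierSpec("linear_svm", {"C": [0.01, 0.1, 1.0, 10.0]}),
        ClassifierSpec("passive_aggressive", {"C": [0.01, 0.1, 1.0]}),
        ClassifierSpec("random_forest", {"n_estimators": [100, 300]}),
        ClassifierSpec("rbf_svm", {"C": [1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}),
        ClassifierSpec("gradient_boosted_trees", {"n_estimators": [100, 300]}),
        ClassifierSpec("gaussian_nb", {"var_smoothing": [1e-9]}),
        ClassifierSpec("neural_net", {"hidden_layer_sizes": [(32,), (64, 32)]}),
    ]


def small_classifier_specs() -> list[ClassifierSpec]:
    """Single-point grids per family, for fast smoke/determinism runs."""
    return [
        ClassifierSpec("logistic", {"C": [1.0]}),
        ClassifierSpec("linear_svm", {"C": [1.0]}),
        ClassifierSpec("passive_aggressive", {"C": [1.0]}),
        ClassifierSpec("random_forest", {"n_estimators": [50]}),
        ClassifierSpec("rbf_svm", {"C": [1.0], "gamma": ["scale"]}),
        ClassifierSpec("gradient_boosted_trees", {"n_estimators": [50]}),
        ClassifierSpec("gaussian_nb", {"var_smoothing": [1e-9]}),
        ClassifierSpec("neural_net", {"hidden_layer_sizes": [(16,)]}),
    ]


def build_classifier(family: str, params: dict, seed: int = 0):
    """Instantiate a family member with ``params`` over the fixed defaults."""
    if family == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if family == "linear_svm":
        return LinearSVC(max_iter=5000, random_state=seed, **params)
    if family == "passive_aggressive":
        # aggressiveness C maps to the pa1 step-size bound eta0
        pa = dict(params)
        eta0 = pa.pop("C", 1.0)
        return SGDClassifier(
            loss="hinge", penalty=None, learning_rate="pa1", eta0=eta0,
            max_iter=1000, random_state=seed, **pa,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "rbf_svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "gradient_boosted_trees":
        return XGBClassifier(
            max_depth=3, learning_rate=0.1, n_jobs=1,
            random_state=seed, eval_metric="logloss", **params,
        )
    if family == "gaussian_nb":
        return GaussianNB(**params)
    if family == "neural_net":
        return MLPClassifier(
            activation="tanh", solver="sgd", learning_rate="adaptive",
            alpha=1e-4, max_iter=500, random_state=seed, **params,
        )
    raise ValueError(f"unknown family {family!r}")


def _cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    params: dict,
    n_folds: int,
    seed: int,
    mode: str,
) -> list[float]:
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores: list[float] = []
    for tr, va in cv.split(X, y):
        X_tr, X_va = X[tr], X[va]
        if mode == "leakage_safe":
            norm = MinMaxNormalizer(mode="leakage_safe").fit(X_tr)
            X_tr, X_va = norm.transform(X_tr), norm.transform(X_va)
        model = spec.build(params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_tr, y[tr])
        scores.append(balanced_accuracy_labels(y[va], model.predict(X_va)))
    return scores


def grid_search_select(
    matrix: DataMatrix,
    atlas=None,
    specs: Sequence[ClassifierSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    mode: str = "paper",
) -> tuple[ModelReport, list[ModelReport]]:
    """Evaluate every (family, grid point); return (best report, all reports).

    ``atlas`` (a NeuroAtlas) restricts the matrix to the selected columns;
    pass None when the matrix is already reduced.  In ``paper`` mode the
    matrix is assumed normalized up front; ``leakage_safe`` renormalizes
    inside each fold.
    """
    if specs is None:
        specs = default_classifier_specs()
    if atlas is not None:
        matrix = matrix.restrict(atlas.selected)
    X, y = matrix.values, matrix.y
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("both classes need at least 2 members for CV")

    reports: list[ModelReport] = []
    for spec in specs:
        for params in spec.points():
            reports.append(
                ModelReport(
                    family=spec.family,
                    params=params,
                    fold_scores=_cv_scores(X, y, spec, params, n_folds, seed, mode),
                    seed=seed,
                    atlas_scope=matrix.scope,
                )
            )
    # best mean; ties -> fewer hyper-parameters, then earlier family
    best = max(
        reports,
        key=lambda r: (r.mean, -len(r.params), -FAMILY_ORDER.index(r.family)),
    )
    return best, reports


class GridSearchClassifier:
    """Estimator facade: fit runs the grid search and refits the winner.

    Attributes: ``best_report_``, ``reports_``, ``best_estimator_``.
    """

    def __init__(self, specs=None, n_folds: int = 5, random_state: int = 0, mode: str = "paper"):
        self.specs = specs
        self.n_folds = n_folds
        self.random_state = random_state
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {
            "specs": self.specs, "n_folds": self.n_folds,
            "random_state": self.random_state, "mode": self.mode,
        }

    def set_params(self, **params) -> "GridSearchClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "GridSearchClassifier":
        if isinstance(X, DataMatrix):
            matrix = X
        else:
            X = np.asarray(X, dtype=float)
            from .registry import canonical_columns

            matrix = DataMatrix(
                scope="global",
                columns=canonical_columns()[: X.shape[1]],
                values=X,
                labels=np.where(np.asarray(y) == 1, "ASD", "TD").astype(object),
                subject_ids=[f"s{i}" for i in range(X.shape[0])],
                sites=["-"] * X.shape[0],
                ages=np.full(X.shape[0], 10.0),
                sexes=["M"] * X.shape[0],
            )
        best, reports = grid_search_select(
            matrix, None, self.specs, self.n_folds, self.random_state, self.mode
        )
        self.best_report_ = best
        self.reports_ = reports
        self.best_estimator_ = build_classifier(best.family, best.params, self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.best_estimator_.fit(matrix.values, matrix.y)
        return self

    def predict(self, X):
        if isinstance(X, DataMatrix):
            X = X.values
        return self.best_estimator_.predict(np.asarray(X, dtype=float))
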