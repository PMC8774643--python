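"""Local surrogate explanations of a classifier's per-subject decision.

To explain why a trained (possibly opaque) classifier calls one subject
ASD or TD, a perturbation neighbourhood is sampled around the subject in
the normalized feature space (Gaussian per column, sd taken from the
training data), each perturbed point is scored by the black-box model,
samples are weighted by an exponential kernel on Euclidean distance from
the subject, and a weighted ridge regression is fitted to the scores.
The contribution of column j is ``coef_j * (x_j - mean_j)``: positive
contributions push the decision toward ASD, negative toward TD.  Column
contributions are rolled up to regions by signed summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .cohort import DataMatrix
from .registry import FeatureColumn


@dataclass
class ExplanationMap:
    """Per-column and per-region contribution scores for one decision."""

    subject_id: str
    contributions: dict[str, float]  # column token -> signed score
    region_scores: dict[str, float]  # region token -> signed sum
    r2: float                        # weighted surrogate fit quality
    n_samples: int
    kernel_width: float
    seed: int


def _model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous decision score, preferring P(ASD) over the margin."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    if callable(model):
        return np.asarray(model(X), dtype=float)
    raise ValueError(
        "model exposes neither predict_proba nor decision_function; "
        "cannot build a surrogate explanation"
    )


class LimeExplainer:
    """Local surrogate explainer fitted to a training matrix.

    Parameters
    ----------
    n_samples : perturbation draws per explanation (default 5000).
    kernel_width : exponential-kernel width; default 0.75 * sqrt(p).
    random_state : seed for the perturbation draws.
    """

    def __init__(self, n_samples: int = 5000, kernel_width: float | None = None,
                 random_state: int = 0):
        self.n_samples = n_samples
        self.kernel_width = kernel_width
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_samples": self.n_samples,
            "kernel_width": self.kernel_width,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "LimeExplainer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "LimeExplainer":
        X = np.asarray(X, dtype=float)
        self.train_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.train_sd_ = np.where(sd > 0, sd, 1e-12)
        p = X.shape[1]
        self.kernel_width_ = (
            self.kernel_width if self.kernel_width is not None else 0.75 * np.sqrt(p)
        )
        return self

    def explain(self, model, x: np.ndarray, columns: Sequence[FeatureColumn],
                subject_id: str = "") -> ExplanationMap:
        """Explain the model's score at point ``x`` (normalized space)."""
        x = np.asarray(x, dtype=float)
        rng = np.random.default_rng(self.random_state)
        Z = rng.normal(loc=x, scale=self.train_sd_, size=(self.n_samples, x.size))
        scores = _model_scores(model, Z)
        dist = np.sqrt(((Z - x) / self.train_sd_) ** 2 @ np.ones(x.size))
        weights = np.exp(-(dist ** 2) / self.kernel_width_ ** 2)

        surrogate = Ridge(alpha=1.0)
        surrogate.fit(Z, scores, sample_weight=weights)
        pred = surrogate.predict(Z)
        w_mean = np.average(scores, weights=weights)
        ss_res = np.average((scores - pred) ** 2, weights=weights)
        ss_tot = np.average((scores - w_mean) ** 2, weights=weights)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        self.surrogate_coef_ = surrogate.coef_.copy()
        contrib = surrogate.coef_ * (x - self.train_mean_)
        contributions = {c.token: float(v) for c, v in zip(columns, contrib)}
        region_scores: dict[str, float] = {}
        for c, v in zip(columns, contrib):
            region_scores[c.region.token] = region_scores.get(c.region.token, 0.0) + float(v)
        return ExplanationMap(
            subject_id=subject_id,
            contributions=contributions,
            region_scores=region_scores,
            r2=float(r2),
            n_samples=self.n_samples,
            kernel_width=float(self.kernel_width_),
            seed=self.random_state,
        )


def explain_subject(
    model,
    matrix: DataMatrix,
    subject_id: str,
    n_samples: int = 5000,
    kernel_width: float | None = None,
    seed: int = 0,
) -> ExplanationMap:
    """Explain one subject's classification against a training matrix."""
    try:
        row = matrix.subject_ids.index(subject_id)
    except ValueError:
        raise KeyError(f"subject {subject_id!r} not in matrix") from None
    x = matrix.values[row]
    if np.isnan(x).any():
        raise ValueError(f"subject {subject_id!r} has missing features")
    explainer = LimeExplainer(
        n_samples=n_samples, kernel_width=kernel_width, random_state=seed
    ).fit(matrix.values)
    return explainer.explain(model, x, matrix.columns, subject_id=subject_id)
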