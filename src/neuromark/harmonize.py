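"""Growth-curve age/sex adjustment and per-column min-max normalization.

Grey-matter volume follows a strong normative age trajectory: it rises
through childhood, peaks in adolescence and declines slowly thereafter,
with male means above female.  Denoting by ``Vs(a)`` the mean cortical
grey-matter volume at age ``a`` for sex ``s``, every regional volume is
replaced by ``V' = V / Vs(a)`` and every regional surface area by
``S' = S / Vs(a)^(2/3)`` (an areal quantity scales with the 2/3 power of a
volume).  Thickness and curvature are left untouched.

After adjustment each column is min-max normalized to [0, 1]:
``f~ = (f - min) / (max - min)``.  The default fits min/max on the full
matrix (faithful to the original protocol); a ``leakage_safe`` mode fits on
training rows only and clips held-out values into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import DataMatrix, SubjectRecord
from .registry import FeatureColumn


@dataclass
class GrowthCurve:
    """Piecewise-linear normative volume trajectory for one sex."""

    sex: str
    ages: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("growth-curve ages must be strictly increasing")
        if not np.all(self.volumes > 0):
            raise ValueError("growth-curve volumes must be strictly positive")


def growth_curve_eval(curve: GrowthCurve, age: float) -> float:
    """Vs(a): linear interpolation between knots, clamped at the ends."""
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    return float(np.interp(age, curve.ages, curve.volumes))


def load_growth_curves(path=None) -> dict[str, GrowthCurve]:
    """Load per-sex growth curves from a TSV (columns ``sex age volume``).

    Without a path the packaged default table is used.  The default is a
    documented stand-in with the canonical trajectory shape (childhood rise,
    adolescent peak, slow decline; male above female) and is intended to be
    replaced with study-specific normative curves where available.
    """
    if path is None:
        ref = resources.files("neuromark.data").joinpath("growth_curves.tsv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    curves = {}
    for sex, sub in frame.groupby("sex"):
        sub = sub.sort_values("age")
        curves[sex] = GrowthCurve(sex=sex, ages=sub["age"].to_numpy(), volumes=sub["volume"].to_numpy())
    if set(curves) != {"M", "F"}:
        raise ValueError("growth-curve table must cover sexes M and F")
    return curves


def adjust_features(
    features: np.ndarray,
    columns: Sequence[FeatureColumn],
    age: float,
    sex: str,
    curves: dict[str, GrowthCurve],
) -> np.ndarray:
    """Divide V columns by Vs(a) and Sa columns by Vs(a)^(2/3)."""
    vs = growth_curve_eval(curves[sex], age)
    if vs <= 0:
        raise ValueError(f"non-positive normative volume Vs({age})={vs}")
    out = np.array(features, dtype=float)
    for j, col in enumerate(columns):
        if col.morphology == "V":
            out[j] = out[j] / vs
        elif col.morphology == "Sa":
            out[j] = out[j] / vs ** (2.0 / 3.0)
    return out


def adjust_record(
    record: SubjectRecord,
    curves: dict[str, GrowthCurve],
    columns: Sequence[FeatureColumn],
) -> SubjectRecord:
    """Age/sex-adjusted copy of ``record``; missing entries stay missing."""
    return replace(
        record,
        features=adjust_features(record.features, columns, record.age, record.sex, curves),
    )


class GrowthCurveAdjuster:
    """Transformer applying the V'/S' growth-curve adjustment to matrices.

    Stateless apart from its curves; follows the fit/transform protocol so
    it can sit in a pipeline (fit is a no-op).
    """

    def __init__(self, curves: dict[str, GrowthCurve] | None = None):
        self.curves = curves

    def get_params(self, deep: bool = True) -> dict:
        return {"curves": self.curves}

    def set_params(self, **params) -> "GrowthCurveAdjuster":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, matrix: DataMatrix, y=None) -> "GrowthCurveAdjuster":
        self.curves_ = self.curves if self.curves is not None else load_growth_curves()
        return self

    def transform(self, matrix: DataMatrix) -> DataMatrix:
        if not hasattr(self, "curves_"):
            self.fit(matrix)
        scale = np.ones_like(matrix.values)
        vs = np.array(
            [growth_curve_eval(self.curves_[s], a) for s, a in zip(matrix.sexes, matrix.ages)]
        )
        for j, col in enumerate(matrix.columns):
            if col.morphology == "V":
                scale[:, j] = vs
            elif col.morphology == "Sa":
                scale[:, j] = vs ** (2.0 / 3.0)
        return DataMatrix(
            scope=matrix.scope,
            columns=list(matrix.columns),
            values=matrix.values / scale,
            labels=matrix.labels.copy(),
            subject_ids=list(matrix.subject_ids),
            sites=list(matrix.sites),
            ages=matrix.ages.copy(),
            sexes=list(matrix.sexes),
        )


class MinMaxNormalizer:
    """Per-column min-max scaling to [0, 1].

    ``mode="paper"`` replicates the original protocol (fit on whatever rows
    are passed to :meth:`fit`, typically the full matrix before CV);
    ``mode="leakage_safe"`` additionally clips transformed values into
    [0, 1], for use when min/max were fitted on training folds only.
    Constant columns map to all-zeros.
    """

    def __init__(self, mode: str = "paper"):
        if mode not in ("paper", "leakage_safe"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {"mode": self.mode}

    def set_params(self, **params) -> "MinMaxNormalizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("normalization requires a complete matrix")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        rng = self.data_max_ - self.data_min_
        self.scale_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (np.asarray(X, dtype=float) - self.data_min_) / self.scale_
        if self.mode == "leakage_safe":
            out = np.clip(out, 0.0, 1.0)
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def normalize_matrix(
    matrix: DataMatrix,
    fit_scope: str | Sequence[int] = "full",
    mode: str = "paper",
) -> tuple[DataMatrix, np.ndarray, np.ndarray]:
    """Min-max normalize a matrix; returns (matrix, per-column min, max).

    ``fit_scope="full"`` fits min/max over all rows; a list of row indices
    fits over those (training) rows only.
    """
    norm = MinMaxNormalizer(mode=mode)
    if isinstance(fit_scope, str):
        if fit_scope != "full":
            raise ValueError(f"unknown fit scope {fit_scope!r}")
        norm.fit(matrix.values)
    else:
        norm.fit(matrix.values[np.asarray(fit_scope, dtype=int)])
    out = DataMatrix(
        scope=matrix.scope,
        columns=list(matrix.columns),
        values=norm.transform(matrix.values),
        labels=matrix.labels.copy(),
        subject_ids=list(matrix.subject_ids),
        sites=list(matrix.sites),
        ages=matrix.ages.copy(),
        sexes=list(matrix.sexes),
    )
    return out, norm.data_min_.copy(), norm.data_max_.copy()
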