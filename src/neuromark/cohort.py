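"""Cohort domain types and plain-text readers/writers.

Cohort tables travel as TSV: an *aggregated* table carries one subject per
row (phenotypes plus the 544 feature columns); a *vertex-level* table is a
long-form list of per-vertex measurements with phenotypes in a companion
table.  Result objects (run reports, neuro-atlases, explanation maps) are
serialised as JSON with sorted keys so identical objects produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import (
    FeatureColumn,
    canonical_columns,
    column_index,
    region_names,
)

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("subject_id", "site", "age", "sex", "dx")
SEXES = ("M", "F")
DIAGNOSES = ("ASD", "TD")


class CohortTableError(ValueError):
    """A cohort table violates the documented schema."""


@dataclass
class SubjectRecord:
    """One subject: phenotypes plus the ordered morphometric feature vector.

    ``features`` is aligned to a column universe (the canonical 544 columns
    unless a reduced universe is in play); missing values are NaN.
    """

    subject_id: str
    site: str
    age: float
    sex: str
    dx: str
    features: np.ndarray

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.dx not in DIAGNOSES:
            raise ValueError(f"dx must be one of {DIAGNOSES}, got {self.dx!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        self.features = np.asarray(self.features, dtype=float)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.features).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0


@dataclass
class DataMatrix:
    """Subjects x feature-columns grid with aligned diagnosis labels.

    ``scope`` is ``"global"`` or ``"site:<name>"``.  After subject exclusion
    the grid contains no missing values.
    """

    scope: str
    columns: list[FeatureColumn]
    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    sites: list[str]
    ages: np.ndarray
    sexes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.ages = np.asarray(self.ages, dtype=float)
        n, p = self.values.shape
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("row count must match label and id counts")
        if len(self.columns) != p:
            raise ValueError("column list length must match value grid width")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary targets: ASD = 1 (positive class), TD = 0."""
        return (self.labels == "ASD").astype(int)

    def restrict(self, columns: Sequence[FeatureColumn]) -> "DataMatrix":
        """A copy restricted to ``columns`` (which must all be present)."""
        idx = column_index(self.columns)
        missing = [c.token for c in columns if c not in idx]
        if missing:
            raise KeyError(f"columns absent from matrix: {missing}")
        sel = [idx[c] for c in columns]
        return DataMatrix(
            scope=self.scope,
            columns=list(columns),
            values=self.values[:, sel].copy(),
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
            sites=list(self.sites),
            ages=self.ages.copy(),
            sexes=list(self.sexes),
        )


@dataclass
class RunReport:
    """Bookkeeping for one pipeline stage: parameters, fold scores, seed."""

    stage: str
    parameters: dict
    fold_scores: list[float]
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores)) if self.fold_scores else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores)) if self.fold_scores else float("nan")


def record_frame(records: Sequence[SubjectRecord], columns: Sequence[FeatureColumn]) -> pd.DataFrame:
    """Records as a wide DataFrame (phenotypes then canonical feature tokens)."""
    data = {
        "subject_id": [r.subject_id for r in records],
        "site": [r.site for r in records],
        "age": [r.age for r in records],
        "sex": [r.sex for r in records],
        "dx": [r.dx for r in records],
    }
    feats = np.array([r.features for r in records], dtype=float)
    for j, col in enumerate(columns):
        data[col.token] = feats[:, j]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def write_cohort_table(
    records: Sequence[SubjectRecord],
    path: str | Path,
    columns: Sequence[FeatureColumn] | None = None,
) -> None:
    """Write an aggregated cohort TSV (missing values as empty cells)."""
    columns = list(columns) if columns is not None else canonical_columns()
    record_frame(records, columns).to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_table(
    path: str | Path,
    dialect: str = "aggregated",
    columns: Sequence[FeatureColumn] | None = None,
):
    """Read a cohort TSV.

    ``dialect="aggregated"`` returns a list of :class:`SubjectRecord`;
    ``dialect="vertex_level"`` returns the long-form vertex DataFrame
    (columns ``subject_id hemi region morph value``).  Feature columns may
    appear in any order in the file; records are always aligned to the
    canonical order.  Unparseable numeric cells become missing values.
    """
    path = Path(path)
    if dialect == "vertex_level":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = ["subject_id", "hemi", "region", "morph", "value"]
        absent = [c for c in required if c not in frame.columns]
        if absent:
            raise CohortTableError(f"{path}: missing vertex-table columns {absent}")
        bad_regions = sorted(set(frame["region"]) - set(region_names()))
        if bad_regions:
            raise CohortTableError(f"{path}: unknown regions {bad_regions}")
        frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
        return frame
    if dialect != "aggregated":
        raise ValueError(f"unknown dialect {dialect!r}")

    frame = pd.read_csv(path, sep="\t", dtype=str)
    absent = [c for c in PHENOTYPE_COLUMNS if c not in frame.columns]
    if absent:
        raise CohortTableError(f"{path}: missing mandatory phenotype columns {absent}")

    feature_tokens = [c for c in frame.columns if c not in PHENOTYPE_COLUMNS]
    if columns is None:
        universe = canonical_columns()
        tokens = {c.token: c for c in universe}
        offenders = sorted(set(feature_tokens) - set(tokens))
        if offenders:
            raise CohortTableError(f"{path}: unknown feature columns {offenders}")
        present = [tokens[t] for t in feature_tokens]
        # canonical subsequence actually present in the file
        columns = [c for c in universe if c in set(present)]
    else:
        columns = list(columns)
        known = {c.token for c in columns}
        offenders = sorted(set(feature_tokens) - known)
        if offenders:
            raise CohortTableError(f"{path}: unknown feature columns {offenders}")

    records: list[SubjectRecord] = []
    for _, row in frame.iterrows():
        feats = np.full(len(columns), np.nan)
        n_bad = 0
        for j, col in enumerate(columns):
            raw = row.get(col.token)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "" or raw == "NA":
                continue
            try:
                feats[j] = float(raw)
            except ValueError:
                n_bad += 1
        if n_bad:
            logger.warning(
                "subject %s: %d unparseable feature cells treated as missing",
                row["subject_id"], n_bad,
            )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                site=str(row["site"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                dx=str(row["dx"]),
                features=feats,
            )
        )
    return records


# ---------------------------------------------------------------------------
# JSON report round-tripping
# ---------------------------------------------------------------------------

def _report_payload(obj) -> dict:
    from .atlas import MarkerTable, NeuroAtlas  # local import to avoid cycle
    from .explain import ExplanationMap

    if isinstance(obj, RunReport):
        return {
            "type": "RunReport",
            "stage": obj.stage,
            "parameters": obj.parameters,
            "fold_scores": list(map(float, obj.fold_scores)),
            "mean": obj.mean,
            "sd": obj.sd,
            "seed": obj.seed,
        }
    if isinstance(obj, NeuroAtlas):
        return {
            "type": "NeuroAtlas",
            "scope": obj.scope,
            "backend": obj.backend,
            "selected": [c.token for c in obj.selected],
            "score_mean": obj.score_mean,
            "score_sd": obj.score_sd,
        }
    if isinstance(obj, ExplanationMap):
        return {
            "type": "ExplanationMap",
            "subject_id": obj.subject_id,
            "contributions": {t: float(v) for t, v in obj.contributions.items()},
            "region_scores": {t: float(v) for t, v in obj.region_scores.items()},
            "r2": float(obj.r2),
            "n_samples": obj.n_samples,
            "kernel_width": float(obj.kernel_width),
            "seed": obj.seed,
        }
    if isinstance(obj, MarkerTable):
        return {
            "type": "MarkerTable",
            "min_local": obj.min_local,
            "table": obj.table.to_dict(orient="list"),
            "mutual_counts": obj.mutual_counts,
        }
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def write_report(obj, path: str | Path) -> None:
    """Serialise a result object to JSON (sorted keys, deterministic bytes)."""
    payload = _report_payload(obj)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_report(path: str | Path):
    """Inverse of :func:`write_report`."""
    from .atlas import MarkerTable, NeuroAtlas
    from .explain import ExplanationMap

    payload = json.loads(Path(path).read_text())
    kind = payload.get("type")
    if kind == "RunReport":
        return RunReport(
            stage=payload["stage"],
            parameters=payload["parameters"],
            fold_scores=[float(v) for v in payload["fold_scores"]],
            seed=int(payload["seed"]),
        )
    if kind == "NeuroAtlas":
        return NeuroAtlas(
            scope=payload["scope"],
            backend=payload["backend"],
            selected=[FeatureColumn.from_token(t) for t in payload["selected"]],
            score_mean=float(payload["score_mean"]),
            score_sd=float(payload["score_sd"]),
        )
    if kind == "ExplanationMap":
        return ExplanationMap(
            subject_id=payload["subject_id"],
            contributions=dict(payload["contributions"]),
            region_scores=dict(payload["region_scores"]),
            r2=float(payload["r2"]),
            n_samples=int(payload["n_samples"]),
            kernel_width=float(payload["kernel_width"]),
            seed=int(payload["seed"]),
        )
    if kind == "MarkerTable":
        return MarkerTable(
            table=pd.DataFrame(payload["table"]),
            mutual_counts={k: int(v) for k, v in payload["mutual_counts"].items()},
            min_local=int(payload["min_local"]),
        )
    raise ValueError(f"{path}: unknown report type {kind!r}")
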