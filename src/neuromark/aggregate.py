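"""Robust regional aggregation: vertex values -> MV-IQR / MV+IQR bounds.

Within-region vertex distributions of cortical measures are typically
skewed, so each (region, morphology) pair is summarised not by mean/sd but
by a robust envelope: the median minus the inter-quartile range (lower
bound) and the median plus the inter-quartile range (upper bound).  Two
bounds per 68 regions x 4 morphologies give the 544-element feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import DataMatrix, SubjectRecord
from .registry import FeatureColumn, RegionId, canonical_columns

logger = logging.getLogger(__name__)


@dataclass
class VertexSampleSet:
    """Per-vertex values of one morphology within one region of one subject."""

    subject_id: str
    region: RegionId
    morphology: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def robust_bounds(values) -> tuple[float, float]:
    """(median - IQR, median + IQR) of ``values``.

    Quartiles use linear interpolation between order statistics (the
    conventional "type 7" rule).  The bounds are a statistical envelope and
    are deliberately not clipped to physically valid ranges.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("robust_bounds requires a non-empty value list")
    mv = float(np.median(arr))
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = float(q3 - q1)
    return mv - iqr, mv + iqr


def build_feature_vector(
    samples: Iterable[VertexSampleSet],
    columns: Sequence[FeatureColumn] | None = None,
) -> np.ndarray:
    """Assemble one subject's ordered feature vector from vertex samples.

    Any (region, morphology) pair absent from ``samples`` yields NaN in both
    of its bound columns; a duplicated pair is an error.
    """
    columns = list(columns) if columns is not None else canonical_columns()
    by_key: dict[tuple[RegionId, str], VertexSampleSet] = {}
    for s in samples:
        key = (s.region, s.morphology)
        if key in by_key:
            raise ValueError(
                f"duplicate vertex sample set for subject {s.subject_id!r}: "
                f"{s.region.token}/{s.morphology}"
            )
        if s.values.size < 10:
            logger.warning(
                "subject %s %s/%s: only %d vertices for aggregation",
                s.subject_id, s.region.token, s.morphology, s.values.size,
            )
        by_key[key] = s

    bounds_cache: dict[tuple[RegionId, str], tuple[float, float]] = {}
    vec = np.full(len(columns), np.nan)
    for j, col in enumerate(columns):
        key = (col.region, col.morphology)
        if key not in by_key:
            continue
        if key not in bounds_cache:
            bounds_cache[key] = robust_bounds(by_key[key].values)
        lo, hi = bounds_cache[key]
        vec[j] = lo if col.bound == "lower" else hi
    return vec


def assemble_matrix(
    records: Sequence[SubjectRecord],
    scope: str = "global",
    columns: Sequence[FeatureColumn] | None = None,
) -> DataMatrix:
    """Stack complete subject records into a data matrix with aligned labels."""
    if not records:
        raise ValueError("cannot assemble a matrix from zero records")
    columns = list(columns) if columns is not None else canonical_columns()
    values = np.array([r.features for r in records], dtype=float)
    if values.shape[1] != len(columns):
        raise ValueError(
            f"records carry {values.shape[1]} features but {len(columns)} "
            "columns were given"
        )
    return DataMatrix(
        scope=scope,
        columns=columns,
        values=values,
        labels=np.array([r.dx for r in records], dtype=object),
        subject_ids=[r.subject_id for r in records],
        sites=[r.site for r in records],
        ages=np.array([r.age for r in records], dtype=float),
        sexes=[r.sex for r in records],
    )


def aggregate_vertex_frame(vertex_frame, phenotypes, columns=None) -> list[SubjectRecord]:
    """Aggregate a long-form vertex table into subject records.

    ``vertex_frame`` has columns ``subject_id hemi region morph value`` (as
    read by :func:`neuromark.cohort.read_cohort_table` with
    ``dialect="vertex_level"``); ``phenotypes`` is a DataFrame with the five
    phenotype columns.
    """
    from .registry import _TOKEN_HEMI, _TOKEN_MORPH  # token decoding maps

    columns = list(columns) if columns is not None else canonical_columns()
    pheno = phenotypes.set_index("subject_id")
    records: list[SubjectRecord] = []
    for sid, sub in vertex_frame.groupby("subject_id", sort=False):
        samples = []
        for (hemi, region, morph), grp in sub.groupby(["hemi", "region", "morph"], sort=False):
            vals = grp["value"].dropna().to_numpy()
            if vals.size == 0:
                continue
            samples.append(
                VertexSampleSet(
                    subject_id=str(sid),
                    region=RegionId(_TOKEN_HEMI[hemi], region),
                    morphology=_TOKEN_MORPH[morph],
                    values=vals,
                )
            )
        row = pheno.loc[str(sid)]
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                site=str(row["site"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                dx=str(row["dx"]),
                features=build_feature_vector(samples, columns),
            )
        )
    return records
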