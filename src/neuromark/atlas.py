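"""Neuro-atlas construction and cross-site marker-frequency analysis.

A neuro-atlas is the set of feature columns selected as discriminative for
one scope: the whole cohort (global) or one acquisition site (local).  For
each scope, RFECV is run under each importance backend and the backend
whose downstream best classifier scores highest defines the scope's atlas.
A column is a candidate imaging marker when the global atlas and at least
``min_local`` local atlases (default 3) all select it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import DataMatrix
from .model_select import ClassifierSpec, grid_search_select
from .registry import FeatureColumn, canonical_columns
from .rfecv import BACKEND_IDS, rfecv_select

logger = logging.getLogger(__name__)


@dataclass
class NeuroAtlas:
    """Selected feature columns for one scope, with the winning backend."""

    scope: str
    backend: str
    selected: list[FeatureColumn]
    score_mean: float
    score_sd: float


@dataclass
class MarkerTable:
    """Per-column selection bookkeeping across the global and local atlases.

    ``table`` columns: token, global_flag, local_count, marker.
    ``mutual_counts``: |global atlas ∩ local atlas| per site.
    """

    table: pd.DataFrame
    mutual_counts: dict[str, int]
    min_local: int

    @property
    def markers(self) -> list[str]:
        return list(self.table.loc[self.table["marker"] == 1, "token"])


def build_scope_atlas(
    matrix: DataMatrix,
    backends: Sequence[str] = BACKEND_IDS,
    rfecv_folds: int = 10,
    model_folds: int = 5,
    seed: int = 0,
    specs: Sequence[ClassifierSpec] | None = None,
    mode: str = "paper",
) -> tuple[NeuroAtlas, dict]:
    """RFECV per backend, then model selection; best backend wins the scope."""
    candidates = []
    detail: dict = {"scope": matrix.scope, "backends": {}}
    for backend in backends:
        res = rfecv_select(matrix, backend, n_folds=rfecv_folds, seed=seed)
        atlas = NeuroAtlas(
            scope=matrix.scope, backend=backend, selected=res.selected,
            score_mean=float("nan"), score_sd=float("nan"),
        )
        best, _ = grid_search_select(
            matrix, atlas, specs=specs, n_folds=model_folds, seed=seed, mode=mode
        )
        atlas.score_mean, atlas.score_sd = best.mean, best.sd
        candidates.append(atlas)
        detail["backends"][backend] = {
            "n_features": res.n_features,
            "best_family": best.family,
            "best_params": best.params,
            "score_mean": best.mean,
            "score_sd": best.sd,
        }
    # max score; ties -> backend order lg1 < lg2 < lsvm < rf
    order = {b: i for i, b in enumerate(BACKEND_IDS)}
    winner = max(candidates, key=lambda a: (a.score_mean, -order[a.backend]))
    detail["winner"] = winner.backend
    return winner, detail


def build_atlases(
    global_matrix: DataMatrix,
    local_matrices: Sequence[DataMatrix],
    backends: Sequence[str] = BACKEND_IDS,
    rfecv_folds: int = 10,
    model_folds: int = 5,
    seed: int = 0,
    specs: Sequence[ClassifierSpec] | None = None,
    mode: str = "paper",
) -> tuple[NeuroAtlas, list[NeuroAtlas], dict]:
    """The global atlas plus one local atlas per site, with a full report."""
    global_atlas, g_detail = build_scope_atlas(
        global_matrix, backends, rfecv_folds, model_folds, seed, specs, mode
    )
    locals_: list[NeuroAtlas] = []
    details = {"global": g_detail, "local": {}}
    for lm in local_matrices:
        atlas, d = build_scope_atlas(
            lm, backends, rfecv_folds, model_folds, seed, specs, mode
        )
        locals_.append(atlas)
        details["local"][lm.scope] = d
    return global_atlas, locals_, details


def common_markers(
    global_atlas: NeuroAtlas,
    local_atlases: Sequence[NeuroAtlas],
    min_local: int = 3,
    universe: Sequence[FeatureColumn] | None = None,
) -> MarkerTable:
    """Marker flags and per-site mutual-feature counts.

    A column is a marker iff it is in the global atlas and in at least
    ``min_local`` local atlases.
    """
    universe = list(universe) if universe is not None else canonical_columns()
    g_set = set(global_atlas.selected)
    local_sets = {a.scope: set(a.selected) for a in local_atlases}
    rows = []
    for col in universe:
        local_count = sum(col in s for s in local_sets.values())
        g_flag = int(col in g_set)
        rows.append({
            "token": col.token,
            "global_flag": g_flag,
            "local_count": local_count,
            "marker": int(g_flag == 1 and local_count >= min_local),
        })
    mutual = {scope: len(g_set & s) for scope, s in local_sets.items()}
    return MarkerTable(table=pd.DataFrame(rows), mutual_counts=mutual, min_local=min_local)


def region_rollup(markers: MarkerTable) -> pd.DataFrame:
    """Markers listed per (morphology, hemisphere, region).

    A region appears once per selected (morphology, bound) column, so
    duplicates are possible; repeated rows are preserved and flagged.
    """
    rows = []
    for token in markers.markers:
        col = FeatureColumn.from_token(token)
        rows.append({
            "morphology": col.morphology,
            "hemisphere": col.region.hemisphere,
            "region": col.region.name,
        })
    frame = pd.DataFrame(rows, columns=["morphology", "hemisphere", "region"])
    if len(frame):
        frame["duplicated"] = frame.duplicated(keep=False)
        n_dup = int(frame["duplicated"].sum())
        if n_dup:
            logger.warning("region rollup contains %d duplicated rows", n_dup)
    return frame
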