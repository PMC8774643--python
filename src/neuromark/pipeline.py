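"""End-to-end orchestration: cohort -> atlases -> classifier -> explanations.

The stages run in the fixed order aggregate -> growth-curve adjustment ->
exclusion/assembly -> min-max normalization -> RFECV atlases -> grid-search
classification -> marker analysis -> per-subject explanations.  Every
stochastic stage derives its seed from the single run seed, so two runs
with the same configuration produce byte-identical JSON reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .assemble import assemble_cohort, cohort_balance_diagnostics, make_local_matrices
from .atlas import MarkerTable, NeuroAtlas, build_atlases, common_markers
from .cohort import DataMatrix, write_report
from .explain import ExplanationMap, explain_subject
from .harmonize import GrowthCurveAdjuster, normalize_matrix
from .model_select import ClassifierSpec, build_classifier, grid_search_select
from .synthetic import SyntheticConfig, generate_cohort


@dataclass
class PipelineSettings:
    """Knobs of one end-to-end run (scale, backends, CV folds, mode)."""

    backends: tuple[str, ...] = ("lg1", "lg2", "lsvm", "rf")
    rfecv_folds: int = 10
    model_folds: int = 5
    specs: Sequence[ClassifierSpec] | None = None
    mode: str = "paper"
    min_local: int = 3
    balance_threshold: float = 0.6
    n_explained_subjects: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    global_matrix: DataMatrix
    local_matrices: list[DataMatrix]
    global_atlas: NeuroAtlas
    local_atlases: list[NeuroAtlas]
    markers: MarkerTable
    details: dict
    explanations: list[ExplanationMap]
    summary: dict


def simulate_end_to_end(
    config: SyntheticConfig,
    settings: PipelineSettings | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Generate a cohort and run the full analysis pipeline on it."""
    settings = settings if settings is not None else PipelineSettings()
    cohort = generate_cohort(config)
    records = cohort.records()
    columns = config.columns()

    # exclusion + assembly, then age/sex adjustment, then normalization
    matrix, exclusion_log = assemble_cohort(
        records, columns, threshold=settings.balance_threshold
    )
    diagnostics = cohort_balance_diagnostics(
        [r for r in records if r.subject_id in set(matrix.subject_ids)]
    )
    matrix = GrowthCurveAdjuster().fit(matrix).transform(matrix)
    matrix, _, _ = normalize_matrix(matrix, fit_scope="full", mode=settings.mode)
    # per-site matrices are rows of the already-normalized global matrix
    locals_ = make_local_matrices(matrix)

    global_atlas, local_atlases, details = build_atlases(
        matrix,
        locals_,
        backends=settings.backends,
        rfecv_folds=settings.rfecv_folds,
        model_folds=settings.model_folds,
        seed=settings.seed,
        specs=settings.specs,
        mode=settings.mode,
    )
    markers = common_markers(
        global_atlas, local_atlases, min_local=settings.min_local, universe=columns
    )

    # refit the global winner and explain a few subjects per site
    best, _ = grid_search_select(
        matrix, global_atlas, specs=settings.specs,
        n_folds=settings.model_folds, seed=settings.seed, mode=settings.mode,
    )
    reduced = matrix.restrict(global_atlas.selected)
    model = build_classifier(best.family, best.params, settings.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(reduced.values, reduced.y)
    explanations: list[ExplanationMap] = []
    for lm in locals_:
        for sid in lm.subject_ids[: settings.n_explained_subjects]:
            explanations.append(
                explain_subject(model, reduced, sid, n_samples=1000, seed=settings.seed)
            )

    summary = {
        "seed": settings.seed,
        "config_seed": config.seed,
        "n_subjects": matrix.n_subjects,
        "n_features": matrix.n_features,
        "n_sites": len(locals_),
        "kept_sites": exclusion_log["kept_sites"],
        "n_dropped_subjects": len(exclusion_log["dropped_subjects"]),
        "n_dropped_sites": len(exclusion_log["dropped_sites"]),
        "diagnosis_counts": {"ASD": diagnostics.n_asd, "TD": diagnostics.n_td},
        "global_backend": global_atlas.backend,
        "global_atlas_size": len(global_atlas.selected),
        "global_best_family": best.family,
        "global_score_mean": best.mean,
        "global_score_sd": best.sd,
        "n_markers": len(markers.markers),
        "mutual_counts": markers.mutual_counts,
    }

    result = PipelineResult(
        global_matrix=matrix,
        local_matrices=locals_,
        global_atlas=global_atlas,
        local_atlases=local_atlases,
        markers=markers,
        details=details,
        explanations=explanations,
        summary=summary,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(result.global_atlas, out_dir / "atlas_global.json")
    for atlas in result.local_atlases:
        site = atlas.scope.split(":", 1)[1]
        write_report(atlas, out_dir / f"atlas_{site}.json")
    write_report(result.markers, out_dir / "markers.json")
    for i, exp in enumerate(result.explanations):
        write_report(exp, out_dir / f"explanation_{i:02d}_{exp.subject_id}.json")
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(result.summary), sort_keys=True, indent=1) + "\n"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
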