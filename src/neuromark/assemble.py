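"""Cohort assembly: exclusion criteria, per-site splits, balance diagnostics.

Two exclusion rules are applied, always in this order: (i) subjects with
any missing feature value are dropped; (ii) a site is dropped when its
majority diagnostic class makes up more than a threshold fraction (default
0.6, strict inequality) of its remaining subjects.  The fraction reading of
the balance rule is used because a literal ASD:TD ratio bound of 0.6 would
discard every near-balanced site.

Balance diagnostics (diagnosis chi-square, Welch age t-test, within-group
sex chi-square) are descriptive only and never gate the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import assemble_matrix
from .cohort import DataMatrix, SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class CohortSummary:
    """Per-site counts and descriptive balance statistics."""

    per_site: pd.DataFrame
    n_total: int
    n_asd: int
    n_td: int
    dx_chi2: float
    dx_chi2_p: float
    age_t: float
    age_t_p: float
    sex_chi2_asd: float
    sex_chi2_asd_p: float
    sex_chi2_td: float
    sex_chi2_td_p: float
    flags: list[str] = field(default_factory=list)


def apply_subject_exclusion(
    records: Sequence[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, str]]]:
    """Drop every subject with at least one missing feature entry."""
    kept: list[SubjectRecord] = []
    dropped: list[tuple[SubjectRecord, str]] = []
    for rec in records:
        if rec.is_complete:
            kept.append(rec)
        else:
            gaps = np.flatnonzero(np.isnan(rec.features))
            shown = ", ".join(map(str, gaps[:10]))
            more = f" (+{len(gaps) - 10} more)" if len(gaps) > 10 else ""
            reason = f"{len(gaps)} missing feature values at columns {shown}{more}"
            dropped.append((rec, reason))
            logger.info("excluding subject %s: %s", rec.subject_id, reason)
    return kept, dropped


def apply_site_exclusion(
    records: Sequence[SubjectRecord],
    threshold: float = 0.6,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Retain sites whose majority-class fraction does not exceed ``threshold``.

    Strict inequality: a site at exactly the threshold is retained.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1), got {threshold}")
    sites: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        sites.setdefault(rec.site, []).append(rec)
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for site, recs in sites.items():
        n = len(recs)
        if n == 0:
            dropped.append((site, "no subjects left after subject exclusion"))
            continue
        n_asd = sum(r.dx == "ASD" for r in recs)
        frac = max(n_asd, n - n_asd) / n
        if frac > threshold:
            dropped.append(
                (site, f"majority-class fraction {frac:.3f} > {threshold} "
                       f"({n_asd} ASD / {n - n_asd} TD)")
            )
            logger.info("excluding site %s: %s", site, dropped[-1][1])
        else:
            kept.append(site)
    return kept, dropped


def assemble_cohort(
    records: Sequence[SubjectRecord],
    columns,
    threshold: float = 0.6,
) -> tuple[DataMatrix, dict]:
    """Subject exclusion, then site exclusion, then the global matrix."""
    kept_subj, dropped_subj = apply_subject_exclusion(records)
    kept_sites, dropped_sites = apply_site_exclusion(kept_subj, threshold)
    final = [r for r in kept_subj if r.site in set(kept_sites)]
    if not final:
        raise ValueError("no subjects remain after exclusion")
    matrix = assemble_matrix(final, scope="global", columns=columns)
    log = {
        "dropped_subjects": [(r.subject_id, reason) for r, reason in dropped_subj],
        "dropped_sites": dropped_sites,
        "kept_sites": sorted(kept_sites),
    }
    return matrix, log


def make_local_matrices(matrix: DataMatrix) -> list[DataMatrix]:
    """Split the global matrix into one per-site matrix (row order kept)."""
    out: list[DataMatrix] = []
    for site in dict.fromkeys(matrix.sites):  # first-appearance order
        rows = [i for i, s in enumerate(matrix.sites) if s == site]
        out.append(
            DataMatrix(
                scope=f"site:{site}",
                columns=list(matrix.columns),
                values=matrix.values[rows],
                labels=matrix.labels[rows],
                subject_ids=[matrix.subject_ids[i] for i in rows],
                sites=[site] * len(rows),
                ages=matrix.ages[rows],
                sexes=[matrix.sexes[i] for i in rows],
            )
        )
    return out


def _sex_chi2(recs: list[SubjectRecord]) -> tuple[float, float, bool]:
    """Chi-square of the sex split against a uniform 50/50 expectation."""
    n_m = sum(r.sex == "M" for r in recs)
    n_f = len(recs) - n_m
    if n_m == 0 or n_f == 0:
        return float("nan"), float("nan"), True
    stat, p = stats.chisquare([n_m, n_f])
    return float(stat), float(p), False


def cohort_balance_diagnostics(records: Sequence[SubjectRecord]) -> CohortSummary:
    """Descriptive demographic balance report (never gates the pipeline)."""
    asd = [r for r in records if r.dx == "ASD"]
    td = [r for r in records if r.dx == "TD"]
    if len(asd) < 2 or len(td) < 2:
        raise ValueError("diagnostics require at least 2 subjects per group")

    rows = []
    for site in sorted({r.site for r in records}):
        recs = [r for r in records if r.site == site]
        s_asd = [r for r in recs if r.dx == "ASD"]
        s_td = [r for r in recs if r.dx == "TD"]
        rows.append({
            "site": site,
            "total": len(recs),
            "n_asd": len(s_asd),
            "n_td": len(s_td),
            "asd_age_min": min((r.age for r in s_asd), default=float("nan")),
            "asd_age_max": max((r.age for r in s_asd), default=float("nan")),
            "td_age_min": min((r.age for r in s_td), default=float("nan")),
            "td_age_max": max((r.age for r in s_td), default=float("nan")),
        })
    per_site = pd.DataFrame(rows)

    flags: list[str] = []
    dx_chi2, dx_p = stats.chisquare([len(asd), len(td)])
    ages_a = np.array([r.age for r in asd])
    ages_t = np.array([r.age for r in td])
    if ages_a.std() == 0 and ages_t.std() == 0:
        # degenerate zero-variance groups: identical means are a null result
        age_t = 0.0 if ages_a.mean() == ages_t.mean() else float("inf")
        age_p = 1.0 if age_t == 0.0 else 0.0
        flags.append("zero age variance in both groups; t-test degenerate")
    else:
        with np.errstate(all="ignore"):
            age_t, age_p = stats.ttest_ind(ages_a, ages_t, equal_var=False)
    sx_a, sx_a_p, deg_a = _sex_chi2(asd)
    sx_t, sx_t_p, deg_t = _sex_chi2(td)
    if deg_a:
        flags.append("ASD group has a single sex; sex chi-square undefined")
    if deg_t:
        flags.append("TD group has a single sex; sex chi-square undefined")

    return CohortSummary(
        per_site=per_site,
        n_total=len(records),
        n_asd=len(asd),
        n_td=len(td),
        dx_chi2=float(dx_chi2),
        dx_chi2_p=float(dx_p),
        age_t=float(age_t),
        age_t_p=float(age_p),
        sex_chi2_asd=sx_a,
        sex_chi2_asd_p=sx_a_p,
        sex_chi2_td=sx_t,
        sex_chi2_td_p=sx_t_p,
        flags=flags,
    )
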