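"""Synthetic multi-site vertex-level morphometry cohorts.

The generator emulates the statistical structure of a multi-site autism
sMRI collection: 12 retained sites with fixed per-site ASD/TD counts and
age ranges, skewed (lognormal) within-region vertex distributions for
surface area and volume, Gaussian thickness and curvature, a normative
age trajectory multiplying volumes (and its 2/3 power multiplying areas),
per-site scanner effects, sex imbalance, optional missing-feature
subjects, and ASD effects planted in configurable (region, morphology)
pairs.  Everything derives from a single seed.

Between-subject variation enters as a multiplicative subject factor per
(region, morphology) pair with sd ``subject_sd``; a planted effect of
standardized size ``d`` multiplies an ASD subject's values by
``1 + direction * d * subject_sd``, so the aggregated feature separates
the groups by roughly ``d`` subject-level standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import VertexSampleSet, build_feature_vector
from .cohort import SubjectRecord
from .harmonize import growth_curve_eval, load_growth_curves
from .registry import (
    FeatureColumn,
    MORPHOLOGIES,
    RegionId,
    canonical_columns,
    reduced_region_names,
    region_names,
)

#: per-vertex base distributions; Sa/V are lognormal (right-skewed, as
#: regional morphometry histograms are), Th/c Gaussian
_BASE_DISTRIBUTIONS = {
    "Sa": ("lognormal", np.log(0.6), 0.35),   # mm^2 per vertex
    "V": ("lognormal", np.log(2.0), 0.35),    # mm^3 per vertex
    "Th": ("normal", 2.5, 0.5),               # mm
    "c": ("normal", 0.12, 0.05),              # 1/mm
}

#: reference volume dividing the growth curve into a dimensionless scale
_V_REF = 560000.0  # male curve at age 20


@dataclass(frozen=True)
class SiteSpec:
    """Per-site subject counts and age ranges for both diagnostic groups."""

    name: str
    n_asd: int
    asd_age_range: tuple[float, float]
    n_td: int
    td_age_range: tuple[float, float]


#: the 12-site reference cohort layout (printed per-site counts and age
#: ranges; totals 664 = 328 ASD + 336 TD)
TABLE1_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("Caltech", 19, (17.5, 55.4), 18, (17.0, 56.2)),
    SiteSpec("CMU", 14, (19.0, 39.0), 13, (20.0, 40.0)),
    SiteSpec("Leuven", 29, (12.1, 32.0), 34, (12.2, 29.0)),
    SiteSpec("MaxMun", 23, (7.0, 58.0), 28, (7.0, 46.0)),
    SiteSpec("OHSU", 12, (8.0, 15.2), 14, (8.2, 11.9)),
    SiteSpec("Olin", 19, (11.0, 24.0), 15, (10.0, 23.0)),
    SiteSpec("Pitt", 29, (9.33, 35.2), 27, (9.4, 33.2)),
    SiteSpec("Stanford", 19, (7.5, 12.9), 19, (7.7, 12.4)),
    SiteSpec("Trinity", 22, (12.0, 23.0), 25, (12.0, 25.6)),
    SiteSpec("UCLA", 53, (8.36, 17.94), 42, (9.2, 17.7)),
    SiteSpec("UM", 61, (8.5, 18.6), 73, (8.2, 28.8)),
    SiteSpec("Yale", 28, (7.0, 17.7), 28, (7.6, 17.8)),
)


@dataclass(frozen=True)
class PlantedEffect:
    """An ASD shift in one (hemisphere, region, morphology) distribution."""

    hemisphere: str
    region: str
    morphology: str
    d: float
    direction: int = 1

    def columns(self) -> list[FeatureColumn]:
        rid = RegionId(self.hemisphere, self.region)
        return [FeatureColumn(rid, self.morphology, b) for b in ("lower", "upper")]


@dataclass
class SyntheticConfig:
    """Everything the generator needs, all derived from one seed."""

    sites: tuple[SiteSpec, ...] = TABLE1_SITES
    regions: tuple[str, ...] | None = None  # None -> all 34 registry regions
    vertex_count_range: tuple[int, int] = (40, 120)
    subject_sd: float = 0.08
    site_effects: bool = True
    site_scale_range: tuple[float, float] = (0.9, 1.1)
    site_offset_frac: float = 0.02
    asd_male_frac: float = 0.8
    td_male_frac: float = 0.8
    planted_effects: tuple[PlantedEffect, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def region_list(self) -> tuple[str, ...]:
        return self.regions if self.regions is not None else region_names()

    def columns(self) -> list[FeatureColumn]:
        return canonical_columns(self.region_list())


def table1_config(**overrides) -> SyntheticConfig:
    """The default 12-site reference configuration."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def reduced_table1_config(scale: float = 0.25, n_regions: int = 4, **overrides) -> SyntheticConfig:
    """A scaled-down 12-site layout (reduced counts and region universe)."""
    sites = tuple(
        SiteSpec(
            s.name,
            max(2, round(s.n_asd * scale)), s.asd_age_range,
            max(2, round(s.n_td * scale)), s.td_age_range,
        )
        for s in TABLE1_SITES
    )
    return replace(
        SyntheticConfig(sites=sites, regions=reduced_region_names(n_regions)),
        **overrides,
    )


def single_site_config(
    n_asd: int,
    n_td: int,
    regions: Sequence[str] | None = None,
    planted_effects: Sequence[PlantedEffect] = (),
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """One balanced site without scanner effects -- the controlled-recovery
    layout used to study selection performance in isolation."""
    return replace(
        SyntheticConfig(
            sites=(SiteSpec("SIM", n_asd, (8.0, 18.0), n_td, (8.0, 18.0)),),
            regions=tuple(regions) if regions is not None else None,
            site_effects=False,
            planted_effects=tuple(planted_effects),
            seed=seed,
        ),
        **overrides,
    )


def default_planted_effects(
    n_pairs: int = 5, d: float = 1.5, regions: Sequence[str] | None = None
) -> tuple[PlantedEffect, ...]:
    """``n_pairs`` (region, morphology) plants = 2*n_pairs planted columns,
    spread over hemispheres and morphologies."""
    names = tuple(regions) if regions is not None else region_names()
    combos = [
        (h, n, m)
        for n in names
        for m in MORPHOLOGIES
        for h in ("left", "right")
    ]
    if n_pairs > len(combos):
        raise ValueError(f"cannot plant {n_pairs} distinct pairs in this universe")
    return tuple(
        PlantedEffect(
            hemisphere=h, region=n, morphology=m, d=d,
            direction=1 if i % 2 == 0 else -1,
        )
        for i, (h, n, m) in enumerate(combos[:n_pairs])
    )


@dataclass
class Cohort:
    """Generated cohort: phenotypes plus per-subject vertex sample sets."""

    phenotypes: pd.DataFrame
    vertex_samples: dict[str, list[VertexSampleSet]]
    config: SyntheticConfig

    def to_vertex_frame(self) -> pd.DataFrame:
        from .registry import _HEMI_TOKEN, _MORPH_TOKEN

        rows = []
        for sid, samples in self.vertex_samples.items():
            for s in samples:
                hemi = _HEMI_TOKEN[s.region.hemisphere]
                morph = _MORPH_TOKEN[s.morphology]
                for v in s.values:
                    rows.append((sid, hemi, s.region.name, morph, v))
        return pd.DataFrame(
            rows, columns=["subject_id", "hemi", "region", "morph", "value"]
        )

    def records(self) -> list[SubjectRecord]:
        cols = self.config.columns()
        out = []
        for _, row in self.phenotypes.iterrows():
            sid = row["subject_id"]
            out.append(
                SubjectRecord(
                    subject_id=sid,
                    site=row["site"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    dx=row["dx"],
                    features=build_feature_vector(self.vertex_samples[sid], cols),
                )
            )
        return out


def _draw_base(rng: np.random.Generator, morph: str, n: int) -> np.ndarray:
    family, a, b = _BASE_DISTRIBUTIONS[morph]
    if family == "lognormal":
        return rng.lognormal(mean=a, sigma=b, size=n)
    return rng.normal(loc=a, scale=b, size=n)


def theoretical_median_iqr(morph: str) -> tuple[float, float]:
    """Closed-form median and IQR of a base vertex distribution."""
    from scipy import stats

    family, a, b = _BASE_DISTRIBUTIONS[morph]
    if family == "lognormal":
        z = stats.norm.ppf([0.25, 0.75])
        q1, q3 = np.exp(a + b * z)
        return float(np.exp(a)), float(q3 - q1)
    z = stats.norm.ppf([0.25, 0.75])
    return float(a), float(b * (z[1] - z[0]))


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a full cohort; reproducible from ``config.seed``."""
    if config.subject_sd <= 0 or not (0 <= config.missing_rate < 1):
        raise ValueError("invalid distribution parameters in config")
    lo, hi = config.vertex_count_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid vertex count range")

    rng = np.random.default_rng(config.seed)
    curves = load_growth_curves()
    regions = [
        RegionId(h, n) for h in ("left", "right") for n in config.region_list()
    ]
    planted = {
        (RegionId(e.hemisphere, e.region), e.morphology): (e.d, e.direction)
        for e in config.planted_effects
    }

    # per-site scanner effects (drawn even when disabled, to keep the draw
    # sequence -- and thus every downstream value -- stable across toggles)
    site_fx: dict[str, dict[str, tuple[float, float]]] = {}
    for site in config.sites:
        fx = {}
        for morph in MORPHOLOGIES:
            scale = rng.uniform(*config.site_scale_range)
            family, loc = _BASE_DISTRIBUTIONS[morph][0], _BASE_DISTRIBUTIONS[morph][1]
            typical = np.exp(loc) if family == "lognormal" else loc
            offset = rng.uniform(-1, 1) * config.site_offset_frac * typical
            fx[morph] = (scale, offset) if config.site_effects else (1.0, 0.0)
        site_fx[site.name] = fx

    pheno_rows = []
    vertex_samples: dict[str, list[VertexSampleSet]] = {}
    for site in config.sites:
        for dx, n_subj, age_range, male_frac in (
            ("ASD", site.n_asd, site.asd_age_range, config.asd_male_frac),
            ("TD", site.n_td, site.td_age_range, config.td_male_frac),
        ):
            for i in range(n_subj):
                sid = f"{site.name}_{dx}{i:03d}"
                age = float(rng.uniform(*age_range))
                sex = "M" if rng.uniform() < male_frac else "F"
                vs_scale = growth_curve_eval(curves[sex], age) / _V_REF
                samples: list[VertexSampleSet] = []
                for region in regions:
                    for morph in MORPHOLOGIES:
                        u = rng.normal(1.0, config.subject_sd)
                        if rng.uniform() < config.missing_rate:
                            continue
                        n_vert = int(rng.integers(lo, hi + 1))
                        vals = _draw_base(rng, morph, n_vert) * u
                        if morph == "V":
                            vals = vals * vs_scale
                        elif morph == "Sa":
                            vals = vals * vs_scale ** (2.0 / 3.0)
                        if dx == "ASD" and (region, morph) in planted:
                            d, direction = planted[(region, morph)]
                            vals = vals * (1.0 + direction * d * config.subject_sd)
                        scale, offset = site_fx[site.name][morph]
                        vals = vals * scale + offset
                        samples.append(
                            VertexSampleSet(
                                subject_id=sid, region=region,
                                morphology=morph, values=vals,
                            )
                        )
                vertex_samples[sid] = samples
                pheno_rows.append(
                    {"subject_id": sid, "site": site.name, "age": age,
                     "sex": sex, "dx": dx}
                )
    phenotypes = pd.DataFrame(pheno_rows)
    return Cohort(phenotypes=phenotypes, vertex_samples=vertex_samples, config=config)


def generate_records(config: SyntheticConfig) -> list[SubjectRecord]:
    """Generate and aggregate in one step (the usual entry point)."""
    return generate_cohort(config).records()
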