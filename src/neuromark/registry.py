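"""Desikan-Killiany region registry and the canonical feature-column universe.

The cortical surface is parcellated into 34 labelled regions per hemisphere
(68 in total).  Each region contributes four morphological measures --
surface area (``Sa``, mm^2), grey-matter volume (``V``, mm^3), cortical
thickness (``Th``, mm) and mean curvature (``c``, 1/mm) -- and each measure
is summarised by two robust bounds (median -/+ inter-quartile range), giving
the canonical universe of 68 x 4 x 2 = 544 feature columns.

Column tokens follow the grammar ``<hemi>_<region>_<morph>_<bound>`` with
``hemi`` in {lh, rh}, ``morph`` in {area, vol, thick, curv} and ``bound`` in
{lo, hi}, e.g. ``lh_bankssts_area_lo``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

HEMISPHERES = ("left", "right")
#: morphology codes in canonical listing order
MORPHOLOGIES = ("Sa", "V", "Th", "c")
BOUNDS = ("lower", "upper")

_HEMI_TOKEN = {"left": "lh", "right": "rh"}
_TOKEN_HEMI = {v: k for k, v in _HEMI_TOKEN.items()}
_MORPH_TOKEN = {"Sa": "area", "V": "vol", "Th": "thick", "c": "curv"}
_TOKEN_MORPH = {v: k for k, v in _MORPH_TOKEN.items()}
_BOUND_TOKEN = {"lower": "lo", "upper": "hi"}
_TOKEN_BOUND = {v: k for k, v in _BOUND_TOKEN.items()}

#: physical units of each morphology
MORPHOLOGY_UNITS = {"Sa": "mm^2", "V": "mm^3", "Th": "mm", "c": "1/mm"}


class RegistryError(RuntimeError):
    """The packaged region registry is missing or corrupted."""


@dataclass(frozen=True, order=True)
class RegionId:
    """One cortical parcel: a hemisphere plus a Desikan-Killiany label."""

    hemisphere: str
    name: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def token(self) -> str:
        return f"{_HEMI_TOKEN[self.hemisphere]}_{self.name}"


@dataclass(frozen=True)
class FeatureColumn:
    """One column of the data matrix: region x morphology x robust bound."""

    region: RegionId
    morphology: str
    bound: str

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.bound not in BOUNDS:
            raise ValueError(f"unknown bound {self.bound!r}")

    @property
    def token(self) -> str:
        return (
            f"{_HEMI_TOKEN[self.region.hemisphere]}_{self.region.name}"
            f"_{_MORPH_TOKEN[self.morphology]}_{_BOUND_TOKEN[self.bound]}"
        )

    @classmethod
    def from_token(cls, token: str) -> "FeatureColumn":
        parts = token.split("_")
        if len(parts) < 4:
            raise ValueError(f"malformed feature-column token {token!r}")
        hemi, morph, bound = parts[0], parts[-2], parts[-1]
        name = "_".join(parts[1:-2])
        if hemi not in _TOKEN_HEMI:
            raise ValueError(f"unknown hemisphere token in {token!r}")
        if morph not in _TOKEN_MORPH:
            raise ValueError(f"unknown morphology token in {token!r}")
        if bound not in _TOKEN_BOUND:
            raise ValueError(f"unknown bound token in {token!r}")
        if name not in region_names():
            raise ValueError(f"unknown region {name!r} in token {token!r}")
        return cls(
            region=RegionId(_TOKEN_HEMI[hemi], name),
            morphology=_TOKEN_MORPH[morph],
            bound=_TOKEN_BOUND[bound],
        )


@lru_cache(maxsize=1)
def region_names() -> tuple[str, ...]:
    """The 34 Desikan-Killiany label names in canonical (alphabetical) order."""
    ref = resources.files("neuromark.data").joinpath("dk_regions.tsv")
    try:
        lines = ref.read_text().splitlines()
    except OSError as exc:  # pragma: no cover
        raise RegistryError(f"cannot read region registry dk_regions.tsv: {exc}") from exc
    if not lines or lines[0].strip() != "name":
        raise RegistryError("corrupted region registry dk_regions.tsv: bad header")
    names = tuple(ln.strip() for ln in lines[1:] if ln.strip())
    if len(names) != 34 or len(set(names)) != 34 or list(names) != sorted(names):
        raise RegistryError(
            "corrupted region registry dk_regions.tsv: expected 34 unique sorted labels"
        )
    return names


def load_region_registry() -> list[RegionId]:
    """All 68 regions, left-hemisphere block first, registry order within."""
    names = region_names()
    return [RegionId(h, n) for h in HEMISPHERES for n in names]


def canonical_columns(regions: Sequence[str] | None = None) -> list[FeatureColumn]:
    """The canonical ordered column universe.

    Ordering is hemisphere (left < right), then region in registry order,
    then morphology (Sa < V < Th < c), then bound (lower < upper).  With all
    34 regions this yields the full 544-column universe; ``regions`` may name
    a subset (e.g. for a reduced test universe), which produces the canonical
    subsequence.
    """
    names = region_names()
    if regions is None:
        use = names
    else:
        unknown = sorted(set(regions) - set(names))
        if unknown:
            raise ValueError(f"unknown region names: {unknown}")
        use = tuple(n for n in names if n in set(regions))
    return [
        FeatureColumn(RegionId(h, n), m, b)
        for h in HEMISPHERES
        for n in use
        for m in MORPHOLOGIES
        for b in BOUNDS
    ]


def column_index(columns: Iterable[FeatureColumn]) -> dict[FeatureColumn, int]:
    return {c: i for i, c in enumerate(columns)}


def reduced_region_names(k: int = 4) -> tuple[str, ...]:
    """First *k* registry label names -- a small universe for fast
    experiments (k=4 yields 8 region-hemisphere parcels = 64 columns)."""
    return region_names()[:k]
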