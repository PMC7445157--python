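"""Municipality -> microregion -> state rollups of valuation results.

Brazilian municipalities are grouped by IBGE into microregions by production
structure and spatial interaction; totals must be conserved exactly at every
level of the hierarchy because all aggregation is done at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Optional, Sequence

from .registry import normalise_name
from .valuation import Totals, ValuationRow, display_round

__all__ = ["RegionHierarchy", "MainCrop", "rollup", "main_crop", "region_share"]

LEVELS = ("municipality", "microregion", "state")


@dataclass
class RegionHierarchy:
    """A partition of municipalities into microregions under a single state root."""

    municipalities: dict[str, tuple[str, str]]  # id -> (name, microregion_id)
    microregions: dict[str, str]  # id -> name
    state: str = "state"

    def __post_init__(self):
        for mun_id, (name, micro_id) in self.municipalities.items():
            if micro_id not in self.microregions:
                raise ValueError(
                    f"municipality {mun_id!r} ({name}) references unknown "
                    f"microregion {micro_id!r}"
                )

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, str, str]], state: str = "state"
    ) -> "RegionHierarchy":
        """Build from (municipality_id, name, microregion_id, microregion_name) rows."""
        municipalities: dict[str, tuple[str, str]] = {}
        microregions: dict[str, str] = {}
        for mun_id, mun_name, micro_id, micro_name in rows:
            if mun_id in municipalities:
                raise ValueError(f"duplicate municipality id {mun_id!r}")
            if microregions.get(micro_id, micro_name) != micro_name:
                raise ValueError(f"conflicting names for microregion {micro_id!r}")
            municipalities[mun_id] = (mun_name, micro_id)
            microregions[micro_id] = micro_name
        return cls(municipalities, microregions, state)

    def microregion_of(self, municipality_id: str) -> str:
        try:
            return self.municipalities[municipality_id][1]
        except KeyError:
            raise KeyError(
                f"unknown municipality id {municipality_id!r} in hierarchy"
            ) from None


def rollup(
    rows: Sequence[ValuationRow], hierarchy: RegionHierarchy, level: str
) -> dict[str, Totals]:
    """Aggregate valuation rows per region at the requested level.

    All aggregation is at full precision. Regions with no rows appear with
    zero totals, so municipality counts are preserved. Rows whose region_id
    is not in the hierarchy raise ``KeyError`` naming it.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")

    if level == "municipality":
        out = {mun_id: Totals() for mun_id in hierarchy.municipalities}
    elif level == "microregion":
        out = {micro_id: Totals() for micro_id in hierarchy.microregions}
    else:
        out = {hierarchy.state: Totals()}

    for row in rows:
        if row.region_id not in hierarchy.municipalities:
            raise KeyError(f"unknown municipality id {row.region_id!r} in hierarchy")
        if level == "municipality":
            key = row.region_id
        elif level == "microregion":
            key = hierarchy.microregion_of(row.region_id)
        else:
            key = hierarchy.state
        tot = out[key]
        tot.total_cpv += row.cpv
        if row.psv_exact is not None:
            tot.total_psv_exact += row.psv_exact
    return out


@dataclass(frozen=True)
class MainCrop:
    """The crop with the largest CPV in a region and its CPV share."""

    crop: str
    share: Decimal  # fraction of region CPV in (0, 1]

    @property
    def share_pct(self) -> int:
        return display_round(self.share * 100)


def main_crop(rows: Sequence[ValuationRow]) -> Optional[MainCrop]:
    """Dominant crop of one region's rows, or ``None`` for a no-production region.

    Ties on CPV are broken lexicographically by normalised crop name, a
    deterministic convention (real data never ties at full dollar precision).
    """
    by_crop: dict[str, Decimal] = {}
    names: dict[str, str] = {}
    for row in rows:
        key = normalise_name(row.crop)
        by_crop[key] = by_crop.get(key, Decimal(0)) + row.cpv
        names.setdefault(key, row.crop)
    total = sum(by_crop.values(), Decimal(0))
    if total == 0:
        return None
    best = min(by_crop, key=lambda k: (-by_crop[k], k))
    return MainCrop(names[best], by_crop[best] / total)


def region_share(region_total, parent_total) -> Decimal:
    """A region's fraction of its parent's total (e.g. microregion PSV / state PSV)."""
    region_total = Decimal(str(region_total))
    parent_total = Decimal(str(parent_total))
    if parent_total <= 0:
        raise ValueError(f"parent total must be positive, got {parent_total}")
    return region_total / parent_total
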