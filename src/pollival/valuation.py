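"""Pollination service value (PSV) from crop production value (CPV).

The dependence-ratio method prices the pollination service embedded in a
crop's market output as PSV = CPV x DR, where DR is the fraction of
production attributable to animal pollinators. Arithmetic is carried out on
``decimal.Decimal`` so that half-dollar products (a CPV ending in 250 or 750
times a DR of 0.05/0.25/0.65/0.95 often ends in .5) are represented exactly.

Two conventions matter for reproducing published tables:

* display rounding is half-AWAY-FROM-ZERO to whole dollars;
* totals are aggregated at full precision and rounded once at the end
  ("aggregate-then-round"), so a state total can be up to n/2 dollars below
  the sum of its display-rounded rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .registry import CropDependenceTable, normalise_name

__all__ = [
    "ProductionRecord",
    "ValuationRow",
    "Totals",
    "crop_psv",
    "display_round",
    "valuate",
    "scenario_without",
    "crop_share",
    "format_percent",
]

_ZERO = Decimal("0")


def _as_money(value) -> Decimal:
    """Coerce to Decimal via str() so float literals do not import binary error."""
    return value if isinstance(value, Decimal) else Decimal(str(value))


@dataclass(frozen=True)
class ProductionRecord:
    """One crop's production value in one region in one year.

    ``data_year_note`` flags records whose value comes from a fallback year
    (the study used 2017 values for three municipalities missing 2016 data);
    such records are valued like any other.
    """

    crop: str
    region_id: str
    year: int
    cpv: Decimal
    data_year_note: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "cpv", _as_money(self.cpv))
        if self.cpv < 0:
            raise ValueError(f"negative production value {self.cpv} for {self.crop!r}")


@dataclass(frozen=True)
class ValuationRow:
    """A production record joined to its DR.

    ``psv_exact`` is exactly ``cpv * dr`` at full precision; ``psv_display``
    is its whole-dollar rounding. Both are ``None`` (absent, not zero) when
    the crop's dependence is unknown.
    """

    crop: str
    region_id: str
    cpv: Decimal
    dr: Optional[Decimal]
    psv_exact: Optional[Decimal]
    psv_display: Optional[int]


@dataclass
class Totals:
    """Aggregate CPV/PSV over a set of valuation rows.

    ``total_psv_exact`` sums full-precision products over rows with a
    defined DR only; unknown-DR crops count toward ``total_cpv`` but are
    excluded (not zeroed) from PSV.
    """

    total_cpv: Decimal = field(default_factory=lambda: _ZERO)
    total_psv_exact: Decimal = field(default_factory=lambda: _ZERO)

    @property
    def total_psv_display(self) -> int:
        return display_round(self.total_psv_exact)

    @property
    def total_cpv_display(self) -> int:
        return display_round(self.total_cpv)

    def __add__(self, other: "Totals") -> "Totals":
        return Totals(
            self.total_cpv + other.total_cpv,
            self.total_psv_exact + other.total_psv_exact,
        )


def crop_psv(cpv, dr) -> Decimal:
    """Pollination service value of one crop: ``cpv * dr``, exact.

    No intermediate rounding; half-dollar results are represented exactly.
    """
    cpv, dr = _as_money(cpv), _as_money(dr)
    if cpv < 0:
        raise ValueError(f"negative crop production value: {cpv}")
    if dr < 0 or dr > 1:
        raise ValueError(f"dependence ratio {dr} outside [0, 1]")
    return cpv * dr


def display_round(value) -> int:
    """Round to the nearest whole dollar, halves away from zero."""
    return int(_as_money(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def valuate(
    records: Sequence[ProductionRecord], deps: CropDependenceTable
) -> tuple[list[ValuationRow], Totals]:
    """Value every record and aggregate totals at full precision.

    Every crop must resolve in ``deps`` (possibly to ``unknown``);
    unresolvable crops raise ``KeyError`` listing all offending names.
    """
    missing = sorted({r.crop for r in records if r.crop not in deps})
    if missing:
        raise KeyError(f"crops missing from dependence table: {missing}")

    rows: list[ValuationRow] = []
    totals = Totals()
    for rec in records:
        dr = deps.dr(rec.crop)
        if dr is None:
            row = ValuationRow(rec.crop, rec.region_id, rec.cpv, None, None, None)
        else:
            exact = crop_psv(rec.cpv, dr)
            row = ValuationRow(
                rec.crop, rec.region_id, rec.cpv, dr, exact, display_round(exact)
            )
            totals.total_psv_exact += exact
        totals.total_cpv += rec.cpv
        rows.append(row)
    return rows, totals


def scenario_without(
    records: Sequence[ProductionRecord],
    deps: CropDependenceTable,
    excluded_crops: Iterable[str],
) -> Totals:
    """Totals in a counterfactual where the named crops are not produced.

    Exclusion is by normalised crop name; excluding an absent crop is a
    no-op. Satisfies totals(all) - totals(excluded) = totals(without) at
    full precision.
    """
    excluded = {normalise_name(c) for c in excluded_crops}
    kept = [r for r in records if normalise_name(r.crop) not in excluded]
    _, totals = valuate(kept, deps)
    return totals


def crop_share(
    rows: Sequence[ValuationRow], crop_or_set: str | Iterable[str], of: str = "psv"
) -> Decimal:
    """Share of total CPV or PSV carried by one crop (or a set of crops).

    PSV shares are taken over rows with a defined DR; CPV shares over all
    rows. Raises ``ValueError`` if the relevant total is zero.
    """
    if of not in ("cpv", "psv"):
        raise ValueError(f"'of' must be 'cpv' or 'psv', got {of!r}")
    names = {crop_or_set} if isinstance(crop_or_set, str) else set(crop_or_set)
    keys = {normalise_name(n) for n in names}

    def value_of(row: ValuationRow) -> Decimal:
        if of == "cpv":
            return row.cpv
        return row.psv_exact if row.psv_exact is not None else _ZERO

    total = sum((value_of(r) for r in rows), _ZERO)
    if total == 0:
        raise ValueError(f"total {of} is zero; share undefined")
    part = sum((value_of(r) for r in rows if normalise_name(r.crop) in keys), _ZERO)
    return part / total


def format_percent(fraction) -> int:
    """Format a fraction as an integer percent, halves away from zero."""
    return int(
        (_as_money(fraction) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
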