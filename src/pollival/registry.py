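"""Pollinator-dependence classes and the crop -> class lookup table.

Crops are binned into categorical dependence classes, each covering a
percentage interval of production attributable to animal pollination and
carrying the interval's midpoint as the dependence ratio (DR) used in
valuation:

====================  ============  ====
class                 interval (%)  DR
====================  ============  ====
essential             90 - 100      0.95
high (alias "great")  40 - 90       0.65
modest                10 - 40       0.25
little                0 - 10        0.05
none                  0             0
unknown               --            --
====================  ============  ====

``unknown`` is a first-class value distinct from ``none``: crops with no
dependence data keep their production value in CPV totals but contribute
nothing (not zero -- nothing) to pollination service value.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "DependenceClass",
    "CropDependenceTable",
    "CLASS_ORDER",
    "CLASSES",
    "get_class",
    "midpoint_ratio",
    "class_from_percentage",
    "load_dependence_table",
    "normalise_name",
]


@dataclass(frozen=True)
class DependenceClass:
    """A categorical pollinator-dependence level.

    ``interval`` is the closed percentage range of production attributable
    to animal pollination; ``midpoint_dr`` is its arithmetic midpoint as a
    fraction, or ``None`` for the ``unknown`` class (never 0).
    """

    label: str
    interval: Optional[tuple[int, int]]
    midpoint_dr: Optional[Decimal]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# Canonical class order: none < little < modest < high < essential.
CLASS_ORDER = ("none", "little", "modest", "high", "essential")

CLASSES: dict[str, DependenceClass] = {
    "essential": DependenceClass("essential", (90, 100), Decimal("0.95")),
    "high": DependenceClass("high", (40, 90), Decimal("0.65")),
    "modest": DependenceClass("modest", (10, 40), Decimal("0.25")),
    "little": DependenceClass("little", (0, 10), Decimal("0.05")),
    "none": DependenceClass("none", (0, 0), Decimal("0")),
    "unknown": DependenceClass("unknown", None, None),
}

# Spellings accepted on input and canonicalised; "great" is the published
# alias of "high" (the açaí class), "no increase" the tabular form of "none".
_LABEL_ALIASES = {
    "great": "high",
    "no increase": "none",
    "none": "none",
    "essential": "essential",
    "high": "high",
    "modest": "modest",
    "little": "little",
    "unknown": "unknown",
}

_VALID_LABELS = "essential, high, modest, little, none, unknown"


def normalise_name(name: str) -> str:
    """Normalise a crop or label for matching: trim, casefold, strip diacritics."""
    stripped = unicodedata.normalize("NFD", name.strip())
    no_marks = "".join(c for c in stripped if not unicodedata.combining(c))
    return no_marks.casefold()


def get_class(label: str) -> DependenceClass:
    """Resolve a (possibly aliased) class label to its :class:`DependenceClass`.

    Raises ``ValueError`` naming the offending label and the six valid ones.
    """
    canonical = _LABEL_ALIASES.get(normalise_name(label))
    if canonical is None:
        raise ValueError(
            f"unrecognised dependence class {label!r}; valid labels are "
            f"{_VALID_LABELS} (aliases: great=high, 'no increase'=none)"
        )
    return CLASSES[canonical]


def midpoint_ratio(cls: DependenceClass | str) -> Optional[Decimal]:
    """Dependence ratio of a class: the interval midpoint as a fraction.

    Returns ``None`` (an explicit undefined marker, never a number) for the
    ``unknown`` class.
    """
    if isinstance(cls, str):
        cls = get_class(cls)
    return cls.midpoint_dr


def class_from_percentage(pct: float | Decimal) -> DependenceClass:
    """Map a dependence percentage in [0, 100] to its class.

    Exact boundary values (10, 40, 90) go to the *higher* class, consistent
    with the published overlapping interval bounds; 0 maps to ``none``.
    """
    pct = Decimal(str(pct)) if not isinstance(pct, Decimal) else pct
    if pct < 0 or pct > 100:
        raise ValueError(f"dependence percentage {pct} outside [0, 100]")
    if pct == 0:
        return CLASSES["none"]
    if pct < 10:
        return CLASSES["little"]
    if pct < 40:
        return CLASSES["modest"]
    if pct < 90:
        return CLASSES["high"]
    return CLASSES["essential"]


@dataclass
class CropDependenceTable:
    """Lookup from (normalised) crop name to dependence class.

    Keys are matched after trimming, casefolding and diacritic stripping;
    the original spelling is preserved for output.
    """

    entries: dict[str, DependenceClass] = field(default_factory=dict)
    display_names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, crop: str) -> bool:
        return normalise_name(crop) in self.entries

    def resolve(self, crop: str) -> DependenceClass:
        key = normalise_name(crop)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"crop {crop!r} not present in dependence table") from None

    def dr(self, crop: str) -> Optional[Decimal]:
        """Dependence ratio for a crop, ``None`` when its class is unknown."""
        return self.resolve(crop).midpoint_dr

    def add(self, crop: str, cls: DependenceClass) -> None:
        key = normalise_name(crop)
        if key in self.entries:
            raise ValueError(f"duplicate crop {crop!r} in dependence table")
        self.entries[key] = cls
        self.display_names[key] = crop.strip()

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {label: 0 for label in (*CLASS_ORDER, "unknown")}
        for cls in self.entries.values():
            counts[cls.label] += 1
        return counts


def load_dependence_table(rows: Iterable[tuple[str, str]]) -> CropDependenceTable:
    """Build a :class:`CropDependenceTable` from (crop, class-label) pairs.

    Duplicate crops (after normalisation) and unrecognised class labels are
    errors. Logs the number of crops per class at INFO.
    """
    table = CropDependenceTable()
    for crop, label in rows:
        table.add(crop, get_class(label))
    counts = {k: v for k, v in table.class_counts().items() if v}
    logger.info("dependence table loaded: %d crops (%s)", len(table), counts)
    return table
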