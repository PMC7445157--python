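"""Municipal GDP-dependence on pollination services.

A municipality's dependence index is 100 * PSV / GDP: the share of its
gross domestic product embodied in crop pollination. The index is NOT
capped at 100 -- where a high-value crop is traded largely informally its
production value can exceed the recorded GDP, a legitimate and diagnostic
outcome (flagged with a warning, never truncated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GDPRecord",
    "DependenceProfile",
    "BANDS",
    "gdp_dependence_pct",
    "band",
    "band_counts",
    "format_pct_2dp",
]

# Finest-applicable band labels, ordered by increasing dependence.
BANDS = ("none", "below_1", "from_1_to_10", "above_10", "above_50")


@dataclass(frozen=True)
class GDPRecord:
    """Total GDP of one municipality in one year, US$."""

    municipality_id: str
    year: int
    gdp: Decimal
    allow_zero: bool = False

    def __post_init__(self):
        object.__setattr__(self, "gdp", Decimal(str(self.gdp)))
        if self.gdp < 0 or (self.gdp == 0 and not self.allow_zero):
            raise ValueError(
                f"GDP for {self.municipality_id!r} must be positive "
                f"(got {self.gdp}); zero requires allow_zero"
            )


@dataclass(frozen=True)
class DependenceProfile:
    """Per-municipality summary: production, service value, GDP share, band."""

    municipality_id: str
    n_crops: int
    cpv: Decimal
    psv: Decimal
    gdp: Decimal
    pct_gdp: Decimal
    band: str
    main_crop: Optional[str] = None
    main_crop_share: Optional[Decimal] = None

    @property
    def informal_market_flag(self) -> bool:
        """True when PSV exceeds GDP, indicating production absent from GDP."""
        return self.pct_gdp > 100


def gdp_dependence_pct(psv, gdp, municipality_id: str = "?") -> Decimal:
    """Dependence index 100 * psv / gdp at full precision.

    May exceed 100 when informally traded production is missing from GDP;
    such cases are logged as warnings but returned unchanged.
    """
    psv, gdp = Decimal(str(psv)), Decimal(str(gdp))
    if gdp <= 0:
        raise ValueError(f"GDP must be positive for municipality {municipality_id!r}")
    if psv < 0:
        raise ValueError(f"PSV must be non-negative, got {psv}")
    pct = 100 * psv / gdp
    if pct > 100:
        logger.warning(
            "municipality %s: PSV exceeds GDP (%.2f%%); production likely "
            "traded informally and absent from GDP",
            municipality_id,
            pct,
        )
    return pct


def band(pct) -> str:
    """Dependence band for an (unrounded) percentage.

    0 -> none; (0,1) -> below_1; [1,10] -> from_1_to_10; (10,50] -> above_10;
    (50,∞) -> above_50. Banding always uses the full-precision percentage;
    two-decimal rounding is presentation only.
    """
    pct = Decimal(str(pct))
    if pct < 0:
        raise ValueError(f"dependence percentage must be non-negative, got {pct}")
    if pct == 0:
        return "none"
    if pct < 1:
        return "below_1"
    if pct <= 10:
        return "from_1_to_10"
    if pct <= 50:
        return "above_10"
    return "above_50"


def band_counts(profiles: Iterable[DependenceProfile | str]) -> dict[str, int]:
    """Count municipalities per band; accepts profiles or bare band labels."""
    counts = {b: 0 for b in BANDS}
    for p in profiles:
        label = p if isinstance(p, str) else p.band
        counts[label] += 1
    return counts


def format_pct_2dp(pct) -> Decimal:
    """Two-decimal presentation of a percentage, halves away from zero."""
    return Decimal(str(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def build_profile(
    municipality_id: str,
    n_crops: int,
    cpv,
    psv,
    gdp,
    main_crop: Optional[str] = None,
    main_crop_share: Optional[Decimal] = None,
) -> DependenceProfile:
    """Assemble a :class:`DependenceProfile`, deriving pct_gdp and band."""
    pct = gdp_dependence_pct(psv, gdp, municipality_id)
    return DependenceProfile(
        municipality_id=municipality_id,
        n_crops=n_crops,
        cpv=Decimal(str(cpv)),
        psv=Decimal(str(psv)),
        gdp=Decimal(str(gdp)),
        pct_gdp=pct,
        band=band(pct),
        main_crop=main_crop,
        main_crop_share=main_crop_share,
    )
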