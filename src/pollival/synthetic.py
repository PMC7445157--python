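"""Synthetic municipality x crop production data with known ground truth.

The study's per-municipality crop values live in supplementary spreadsheets
that are not redistributable, so this module emulates their statistical
structure: ~144 municipalities partitioned into ~22 microregions,
heavy-tailed (log-normal) per-crop production values, a per-municipality
crop count in the observed 1-23 range, occasional municipalities dominated
by a single pollinator-dependent crop (>97% of CPV), a small probability of
a no-production municipality, and an informal-market fraction of the
dominant crop's value that is absent from recorded GDP (which can push the
GDP-dependence index past 100%).

Every generated dataset carries a ``ground_truth`` block computed by an
independent brute-force pass (plain loops over the raw rows, no shared code
with the pipeline) so that pipeline-recovery tests are a genuine oracle.

The module also ships the published state-level tables as typed fixtures
(:func:`fixture_tables`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from typing import Optional

import numpy as np

from .registry import CropDependenceTable, load_dependence_table
from .valuation import ProductionRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "fixture_tables",
    "fixture_dependence_table",
    "fixture_production_records",
    "Table1Row",
    "Table2Row",
    "Table3Row",
]

_STATE_REGION = "para-state"


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    """One state-level crop: class label, CPV, and the printed PSV (None if unknown)."""

    crop: str
    dependence_class: str
    cpv: Decimal
    psv_printed: Optional[Decimal]


@dataclass(frozen=True)
class Table2Row:
    """One microregion's total CPV and PSV."""

    microregion: str
    cpv: Decimal
    psv: Decimal


@dataclass(frozen=True)
class Table3Row:
    """One highly dependent municipality, as published."""

    municipality: str
    n_crops: int
    gdp: Decimal
    cpv: Decimal
    main_crop: str
    main_crop_pct: int
    psv: Decimal
    pct_gdp: Decimal


def _read_packaged(name: str) -> list[dict[str, str]]:
    text = resources.files("pollival.data").joinpath(name).read_text(encoding="utf-8")
    return list(csv.DictReader(text.splitlines()))


def fixture_tables() -> tuple[list[Table1Row], list[Table2Row], list[Table3Row]]:
    """The packaged study tables: 36 crops, 22 microregions, 13 municipalities."""
    t1 = [
        Table1Row(
            r["crop"],
            r["dependence_class"],
            Decimal(r["cpv_usd"]),
            Decimal(r["psv_usd"]) if r["psv_usd"] else None,
        )
        for r in _read_packaged("table1_crops.csv")
    ]
    t2 = [
        Table2Row(r["microregion"], Decimal(r["cpv_usd"]), Decimal(r["psv_usd"]))
        for r in _read_packaged("table2_microregions.csv")
    ]
    t3 = [
        Table3Row(
            r["municipality"],
            int(r["n_crops"]),
            Decimal(r["gdp_usd"]),
            Decimal(r["cpv_usd"]),
            r["main_crop"],
            int(r["main_crop_pct"]),
            Decimal(r["psv_usd"]),
            Decimal(r["pct_gdp"]),
        )
        for r in _read_packaged("table3_municipalities.csv")
    ]
    return t1, t2, t3


def fixture_dependence_table() -> CropDependenceTable:
    """The packaged 36-crop dependence table (canonical class labels)."""
    rows = [(r["crop"], r["dependence_class"]) for r in _read_packaged("dependence_table.csv")]
    return load_dependence_table(rows)


def fixture_production_records(year: int = 2016) -> list[ProductionRecord]:
    """State-level production records built from the packaged crop table."""
    return [
        ProductionRecord(row.crop, _STATE_REGION, year, row.cpv)
        for row in fixture_tables()[0]
    ]


def fixture_hierarchy_rows() -> list[tuple[str, str, str, str]]:
    """Rows of the packaged municipality -> microregion hierarchy."""
    return [
        (r["municipality_id"], r["municipality_name"], r["microregion_id"], r["microregion_name"])
        for r in _read_packaged("hierarchy_para.csv")
    ]


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _default_catalog() -> list[tuple[str, str]]:
    return [(r["crop"], r["dependence_class"]) for r in _read_packaged("dependence_table.csv")]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study's reported structure.

    ``production_scale`` and ``gdp_base`` are (mu, sigma) of log-normal
    distributions in log-dollars: per-crop municipal production values with
    median ~US$200k and a heavy right tail, and non-agricultural GDP with
    median ~US$100M. ``dominance_prob``/``dominance_share`` reproduce the
    handful of municipalities where a single pollinator-dependent crop
    carries 97-99% of CPV; ``zero_production_prob`` matches one
    no-production municipality out of 144; ``informal_fraction`` is the
    share of the dominant crop's value missing from recorded GDP.
    """

    n_municipalities: int = 144
    n_microregions: int = 22
    crop_catalog: list[tuple[str, str]] = field(default_factory=_default_catalog)
    production_scale: tuple[float, float] = (12.2, 2.0)
    dominance_prob: float = 0.09
    dominance_share: tuple[float, float] = (0.97, 0.99)
    zero_production_prob: float = 1.0 / 144.0
    informal_fraction: float = 0.5
    gdp_base: tuple[float, float] = (18.4, 1.0)
    max_crops_per_municipality: int = 23
    year: int = 2016

    def validate(self) -> None:
        for name in ("dominance_prob", "zero_production_prob", "informal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_microregions > self.n_municipalities:
            raise ValueError(
                f"n_microregions ({self.n_microregions}) exceeds "
                f"n_municipalities ({self.n_municipalities})"
            )
        if self.n_microregions < 1 or self.n_municipalities < 1:
            raise ValueError("need at least one municipality and one microregion")
        if not self.crop_catalog:
            raise ValueError("crop catalog is empty")
        lo, hi = self.dominance_share
        if not (0 < lo <= hi < 1):
            raise ValueError(f"dominance_share must satisfy 0 < lo <= hi < 1, got {lo, hi}")


@dataclass
class SyntheticDataset:
    """Generated tables (as plain CSV-schema rows) plus brute-force ground truth."""

    production_rows: list[tuple]  # municipality_id, name, microregion_id, crop, year, value_usd
    gdp_rows: list[tuple]  # municipality_id, year, gdp_usd
    hierarchy_rows: list[tuple]  # municipality_id, name, microregion_id, microregion_name
    dependence_rows: list[tuple]  # crop, class label
    ground_truth: dict

    def production_records(self) -> list[ProductionRecord]:
        return [
            ProductionRecord(crop, mun_id, year, Decimal(value))
            for mun_id, _name, _micro, crop, year, value in self.production_rows
        ]


# Brute-force DR lookup, deliberately separate from the registry.
_BRUTE_DR = {
    "essential": Decimal("0.95"),
    "high": Decimal("0.65"),
    "great": Decimal("0.65"),
    "modest": Decimal("0.25"),
    "little": Decimal("0.05"),
    "none": Decimal("0"),
    "no increase": Decimal("0"),
}


def _brute_force_truth(dataset_rows, gdp_rows, hierarchy_rows, dependence_rows) -> dict:
    """Ground truth by direct summation over raw rows; shares no pipeline code."""
    dr_of = {}
    for crop, label in dependence_rows:
        dr_of[crop] = _BRUTE_DR.get(label.strip().lower())  # None for unknown

    mun_cpv: dict[str, Decimal] = {}
    mun_psv: dict[str, Decimal] = {}
    mun_crop_cpv: dict[str, dict[str, Decimal]] = {}
    for mun_id, _name, _micro, crop, _year, value in dataset_rows:
        v = Decimal(value)
        mun_cpv[mun_id] = mun_cpv.get(mun_id, Decimal(0)) + v
        dr = dr_of[crop]
        if dr is not None:
            mun_psv[mun_id] = mun_psv.get(mun_id, Decimal(0)) + v * dr
        mun_crop_cpv.setdefault(mun_id, {})
        mun_crop_cpv[mun_id][crop] = mun_crop_cpv[mun_id].get(crop, Decimal(0)) + v

    micro_of = {mun_id: micro for mun_id, _n, micro, _mn in hierarchy_rows}
    micro_cpv: dict[str, Decimal] = {m: Decimal(0) for _i, _n, m, _mn in hierarchy_rows}
    micro_psv: dict[str, Decimal] = {m: Decimal(0) for _i, _n, m, _mn in hierarchy_rows}
    state_cpv = Decimal(0)
    state_psv = Decimal(0)

    truth_mun = {}
    for mun_id, _name, micro, _mn in hierarchy_rows:
        cpv = mun_cpv.get(mun_id, Decimal(0))
        psv = mun_psv.get(mun_id, Decimal(0))
        micro_cpv[micro] += cpv
        micro_psv[micro] += psv
        state_cpv += cpv
        state_psv += psv
        main, main_share = None, None
        crops = mun_crop_cpv.get(mun_id, {})
        if cpv > 0:
            best = sorted(crops.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            main, main_share = best[0], str(best[1] / cpv)
        truth_mun[mun_id] = {
            "cpv": str(cpv),
            "psv": str(psv),
            "n_crops": len(crops),
            "main_crop": main,
            "main_crop_share": main_share,
        }

    for mun_id, _year, gdp in gdp_rows:
        pct = 100 * Decimal(truth_mun[mun_id]["psv"]) / Decimal(gdp)
        truth_mun[mun_id]["gdp"] = str(gdp)
        truth_mun[mun_id]["pct_gdp"] = str(pct)

    return {
        "municipalities": truth_mun,
        "microregions": {
            m: {"cpv": str(micro_cpv[m]), "psv": str(micro_psv[m])} for m in micro_cpv
        },
        "state": {"cpv": str(state_cpv), "psv": str(state_psv)},
    }


def generate(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a full synthetic dataset, reproducible for a fixed seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n_mun, n_micro = config.n_municipalities, config.n_microregions
    micro_ids = [f"mr{j:03d}" for j in range(1, n_micro + 1)]

    # Partition: two municipalities per microregion first (when feasible),
    # remainder assigned uniformly at random.
    assignment: list[str] = []
    if n_mun >= 2 * n_micro:
        assignment.extend(micro_ids * 2)
    else:
        assignment.extend(micro_ids[:n_mun])
    while len(assignment) < n_mun:
        assignment.append(micro_ids[int(rng.integers(0, n_micro))])
    rng.shuffle(assignment)

    catalog = list(config.crop_catalog)
    crop_names = [c for c, _ in catalog]
    dependent_idx = [
        i for i, (_, label) in enumerate(catalog)
        if _BRUTE_DR.get(label.strip().lower()) not in (None, Decimal(0))
    ]
    mu, sigma = config.production_scale
    gmu, gsigma = config.gdp_base

    production_rows, gdp_rows, hierarchy_rows = [], [], []
    for i in range(n_mun):
        mun_id = f"mun{i + 1:03d}"
        name = f"Municipality {i + 1}"
        micro = assignment[i]
        hierarchy_rows.append((mun_id, name, micro, f"Microregion {micro[2:].lstrip('0')}"))

        base_gdp = max(1, int(round(float(rng.lognormal(gmu, gsigma)))))
        if rng.random() < config.zero_production_prob:
            gdp_rows.append((mun_id, config.year, base_gdp))
            continue

        n_crops = int(rng.integers(1, min(config.max_crops_per_municipality, len(catalog)) + 1))
        chosen = list(rng.choice(len(catalog), size=n_crops, replace=False))

        dominated = bool(rng.random() < config.dominance_prob) and dependent_idx
        dominant: Optional[int] = None
        if dominated:
            in_draw = [c for c in chosen if c in dependent_idx]
            if in_draw:
                dominant = int(in_draw[int(rng.integers(0, len(in_draw)))])
            else:
                dominant = int(dependent_idx[int(rng.integers(0, len(dependent_idx)))])
                chosen.append(dominant)

        values: dict[int, int] = {}
        for c in chosen:
            if c == dominant:
                continue
            v = float(rng.lognormal(mu, sigma))
            values[c] = max(250, int(round(v / 250.0)) * 250)

        informal_excluded = 0
        if dominant is not None:
            others = sum(values.values())
            lo, hi = config.dominance_share
            s = float(rng.uniform(lo, hi))
            if others == 0:  # single-crop municipality: fully dominant
                dom_value = max(250, int(round(float(rng.lognormal(mu, sigma)) / 250.0)) * 250)
            else:
                dom_value = int(math.ceil(s / (1.0 - s) * others))
            values[dominant] = dom_value
            informal_excluded = int(round(config.informal_fraction * dom_value))

        total_cpv = sum(values.values())
        for c in sorted(values):
            production_rows.append(
                (mun_id, name, micro, crop_names[c], config.year, values[c])
            )
        gdp = max(1, base_gdp + total_cpv - informal_excluded)
        gdp_rows.append((mun_id, config.year, gdp))

    truth = _brute_force_truth(production_rows, gdp_rows, hierarchy_rows, catalog)
    return SyntheticDataset(production_rows, gdp_rows, hierarchy_rows, catalog, truth)
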