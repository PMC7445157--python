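"""Strict CSV readers/writers and the end-to-end pipeline driver.

All monetary fields travel as exact decimals: values are parsed with
``decimal.Decimal`` straight from the CSV text (never through binary
floats) and serialised back as whole dollars. Readers validate headers and
report the 1-based line number of any offending row. CSV dialect is
comma-separated UTF-8 with ``"`` quoting.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Optional, Sequence

from .dependence import DependenceProfile, build_profile, format_pct_2dp
from .registry import CropDependenceTable, load_dependence_table, normalise_name
from .spatial import RegionHierarchy, main_crop, rollup
from .valuation import (
    ProductionRecord,
    Totals,
    ValuationRow,
    display_round,
    scenario_without,
    valuate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "read_production_csv",
    "read_dependence_csv",
    "read_gdp_csv",
    "read_hierarchy_csv",
    "write_production_csv",
    "write_gdp_csv",
    "write_hierarchy_csv",
    "write_dependence_csv",
    "write_valuation_report",
    "write_profiles_csv",
    "run_pipeline",
]


class CsvFormatError(ValueError):
    """A malformed row or header in an input CSV, with file and line context."""


def _open_reader(path: Path, required: Sequence[str]) -> tuple[csv.DictReader, list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {missing}")
    return reader, header


def _parse_money(raw: str, path: Path, lineno: int, column: str) -> Decimal:
    raw = raw.strip()
    try:
        value = Decimal(raw)
    except (InvalidOperation, ValueError):
        raise CsvFormatError(
            f"{path}, line {lineno}: cannot parse {column}={raw!r} as a decimal "
            "(thousands separators are not accepted)"
        ) from None
    if value < 0:
        raise CsvFormatError(f"{path}, line {lineno}: negative {column} {raw}")
    return value


def read_production_csv(path: str | Path) -> list[ProductionRecord]:
    """Read production records; value_usd is parsed as an exact decimal."""
    path = Path(path)
    reader, _ = _open_reader(path, ["municipality_id", "crop", "year", "value_usd"])
    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            year = int(row["year"])
        except ValueError:
            raise CsvFormatError(
                f"{path}, line {lineno}: cannot parse year={row['year']!r}"
            ) from None
        records.append(
            ProductionRecord(
                crop=row["crop"],
                region_id=row["municipality_id"],
                year=year,
                cpv=_parse_money(row["value_usd"], path, lineno, "value_usd"),
                data_year_note=(row.get("data_year_note") or None),
            )
        )
    logger.info("read %d production records from %s", len(records), path)
    return records


def read_dependence_csv(path: str | Path) -> CropDependenceTable:
    path = Path(path)
    reader, _ = _open_reader(path, ["crop", "dependence_class"])
    return load_dependence_table(
        (row["crop"], row["dependence_class"]) for row in reader
    )


def read_gdp_csv(path: str | Path) -> dict[str, Decimal]:
    """Read per-municipality GDP; returns municipality_id -> GDP (US$)."""
    path = Path(path)
    reader, _ = _open_reader(path, ["municipality_id", "year", "gdp_usd"])
    gdp: dict[str, Decimal] = {}
    for lineno, row in enumerate(reader, start=2):
        mun = row["municipality_id"]
        if mun in gdp:
            raise CsvFormatError(f"{path}, line {lineno}: duplicate municipality {mun!r}")
        gdp[mun] = _parse_money(row["gdp_usd"], path, lineno, "gdp_usd")
    return gdp


def read_hierarchy_csv(path: str | Path) -> RegionHierarchy:
    path = Path(path)
    reader, _ = _open_reader(
        path, ["municipality_id", "municipality_name", "microregion_id", "microregion_name"]
    )
    return RegionHierarchy.from_rows(
        (
            row["municipality_id"],
            row["municipality_name"],
            row["microregion_id"],
            row["microregion_name"],
        )
        for row in reader
    )


def _write_csv(path: Path, header: Sequence[str], rows) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(header)
        writer.writerows(rows)


def write_production_csv(path: str | Path, rows) -> None:
    """Rows: (municipality_id, municipality_name, microregion, crop, year, value_usd)."""
    _write_csv(
        Path(path),
        ["municipality_id", "municipality_name", "microregion", "crop", "year", "value_usd"],
        rows,
    )


def write_gdp_csv(path: str | Path, rows) -> None:
    _write_csv(Path(path), ["municipality_id", "year", "gdp_usd"], rows)


def write_hierarchy_csv(path: str | Path, rows) -> None:
    _write_csv(
        Path(path),
        ["municipality_id", "municipality_name", "microregion_id", "microregion_name"],
        rows,
    )


def write_dependence_csv(path: str | Path, rows) -> None:
    _write_csv(Path(path), ["crop", "dependence_class"], rows)


def write_valuation_report(path: str | Path, rows: Sequence[ValuationRow]) -> None:
    """Per-row valuation report; money as whole dollars, DR blank when unknown."""
    _write_csv(
        Path(path),
        ["crop", "region_id", "cpv_usd", "dr", "psv_usd"],
        (
            (
                r.crop,
                r.region_id,
                display_round(r.cpv),
                "" if r.dr is None else str(r.dr),
                "" if r.psv_display is None else r.psv_display,
            )
            for r in rows
        ),
    )


def write_profiles_csv(path: str | Path, profiles: Sequence[DependenceProfile],
                       names: Optional[dict[str, str]] = None) -> None:
    """Municipality dependence report mirroring the published layout."""
    names = names or {}
    _write_csv(
        Path(path),
        [
            "municipality_id", "municipality_name", "n_crops", "gdp_usd", "cpv_usd",
            "main_crop", "main_crop_pct", "psv_usd", "pct_gdp", "band",
        ],
        (
            (
                p.municipality_id,
                names.get(p.municipality_id, ""),
                p.n_crops,
                display_round(p.gdp),
                display_round(p.cpv),
                p.main_crop or "",
                "" if p.main_crop_share is None else display_round(p.main_crop_share * 100),
                display_round(p.psv),
                str(format_pct_2dp(p.pct_gdp)),
                p.band,
            )
            for p in profiles
        ),
    )


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs, scenario exclusions and output destinations for one run."""

    production_path: Path
    dependence_path: Path
    gdp_path: Optional[Path] = None
    hierarchy_path: Optional[Path] = None
    exclude_crops: list[str] = field(default_factory=list)
    out_dir: Path = Path("reports")
    formats: tuple[str, ...] = ("csv", "json")


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run."""

    rows: list[ValuationRow]
    totals: Totals
    by_municipality: Optional[dict[str, Totals]] = None
    by_microregion: Optional[dict[str, Totals]] = None
    profiles: Optional[list[DependenceProfile]] = None
    scenarios: dict[str, Totals] = field(default_factory=dict)

    def totals_json(self) -> dict:
        psv_over_cpv = (
            None
            if self.totals.total_cpv == 0
            else float(self.totals.total_psv_exact / self.totals.total_cpv)
        )
        per_crop: dict[str, dict] = {}
        for r in self.rows:
            agg = per_crop.setdefault(
                r.crop, {"cpv": Decimal(0), "psv": Decimal(0) if r.dr is not None else None}
            )
            agg["cpv"] += r.cpv
            if r.psv_exact is not None:
                agg["psv"] = (agg["psv"] or Decimal(0)) + r.psv_exact
        return {
            "total_cpv": self.totals.total_cpv_display,
            "total_psv": self.totals.total_psv_display,
            "psv_over_cpv": psv_over_cpv,
            "per_crop": [
                {
                    "crop": crop,
                    "cpv": display_round(v["cpv"]),
                    "psv": None if v["psv"] is None else display_round(v["psv"]),
                }
                for crop, v in sorted(per_crop.items())
            ],
            "scenarios": {
                name: {"total_cpv": t.total_cpv_display, "total_psv": t.total_psv_display}
                for name, t in self.scenarios.items()
            },
        }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the pipeline stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute valuate -> rollup -> dependence index -> scenarios and write reports."""
    with _stage("read"):
        records = read_production_csv(config.production_path)
        deps = read_dependence_csv(config.dependence_path)
        hierarchy = (
            read_hierarchy_csv(config.hierarchy_path) if config.hierarchy_path else None
        )
        gdp = read_gdp_csv(config.gdp_path) if config.gdp_path else None
    if not records:
        logger.warning("empty production file %s: reports will be empty", config.production_path)

    with _stage("valuate"):
        rows, totals = valuate(records, deps)
    logger.info(
        "valuated %d records: CPV %s, PSV %s",
        len(rows), totals.total_cpv_display, totals.total_psv_display,
    )

    bundle = ReportBundle(rows=rows, totals=totals)

    if hierarchy is not None:
        with _stage("rollup"):
            bundle.by_municipality = rollup(rows, hierarchy, "municipality")
            bundle.by_microregion = rollup(rows, hierarchy, "microregion")

    if gdp is not None and hierarchy is not None:
        with _stage("dependence_index"):
            profiles = []
            rows_by_mun: dict[str, list[ValuationRow]] = {}
            for r in rows:
                rows_by_mun.setdefault(r.region_id, []).append(r)
            for mun_id, tot in bundle.by_municipality.items():
                if mun_id not in gdp:
                    logger.warning("no GDP record for municipality %s; skipped", mun_id)
                    continue
                mc = main_crop(rows_by_mun.get(mun_id, []))
                profiles.append(
                    build_profile(
                        mun_id,
                        n_crops=len({r.crop for r in rows_by_mun.get(mun_id, [])}),
                        cpv=tot.total_cpv,
                        psv=tot.total_psv_exact,
                        gdp=gdp[mun_id],
                        main_crop=None if mc is None else mc.crop,
                        main_crop_share=None if mc is None else mc.share,
                    )
                )
            profiles.sort(key=lambda p: -p.pct_gdp)
            bundle.profiles = profiles

    with _stage("scenarios"):
        for crop in config.exclude_crops:
            bundle.scenarios[f"without {crop}"] = scenario_without(records, deps, [crop])

    with _stage("write"):
        out = Path(config.out_dir)
        if "csv" in config.formats:
            write_valuation_report(out / "valuation.csv", rows)
            if bundle.by_microregion is not None:
                _write_csv(
                    out / "microregions.csv",
                    ["microregion_id", "microregion_name", "cpv_usd", "psv_usd"],
                    (
                        (mid, hierarchy.microregions[mid],
                         t.total_cpv_display, t.total_psv_display)
                        for mid, t in sorted(bundle.by_microregion.items())
                    ),
                )
            if bundle.profiles is not None:
                mun_names = {mid: nm for mid, (nm, _) in hierarchy.municipalities.items()}
                write_profiles_csv(out / "municipalities.csv", bundle.profiles, mun_names)
        if "json" in config.formats:
            out.mkdir(parents=True, exist_ok=True)
            (out / "totals.json").write_text(
                json.dumps(bundle.totals_json(), indent=2, ensure_ascii=False) + "\n",
                encoding="utf-8",
            )
    return bundle
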