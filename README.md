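# pollival

Economic valuation of crop pollination services for the Eastern Amazon
(Pará state, Brazil), built as a reusable, tested pipeline.

At least three quarters of leading crops depend to some degree on animal
pollinators, and in Pará the dominant crop — açaí (*Euterpe oleracea*) — is
highly pollinator-dependent and traded largely on informal markets. This
package answers two questions for analysts, ecologists and regional
planners: how much of a region's crop production value is attributable to
animal pollination, and which municipalities' economies depend most on that
service.

## Method

The core is the **dependence-ratio** valuation (Gallai & Vaissière style):

    PSV = CPV × DR

where CPV is a crop's annual production value (US$), DR is the fraction of
production attributable to animal pollinators, and PSV is the pollination
service value. DRs come from categorical dependence classes (Klein-style):
*essential* 90–100% → DR 0.95, *high* ("great") 40–90% → 0.65, *modest*
10–40% → 0.25, *little* 0–10% → 0.05, *none* → 0; crops with *unknown*
dependence are excluded from PSV (not zeroed) but kept in CPV totals.

On top of the per-crop valuation the package provides:

- **spatial rollups** over a municipality → microregion → state hierarchy,
  with exact conservation of totals at every level;
- a **GDP-dependence index** per municipality, 100 × PSV / GDP, banded into
  none / <1% / 1–10% / >10% / >50% (uncapped: informal trade can push it
  past 100%);
- **crop-exclusion scenarios** ("what would PSV be without açaí?");
- a **seeded synthetic-data generator** emulating the study region's
  structure (144 municipalities in 22 microregions, heavy-tailed production
  values, single-crop dominance, informal-market GDP gaps), with an
  independent brute-force ground truth for end-to-end verification.

All monetary arithmetic uses exact decimals; display rounding is
half-away-from-zero, and totals are aggregated at full precision before a
single final rounding ("aggregate-then-round") — the convention needed to
reproduce published tables to the dollar.

## Worked example

```python
>>> import pollival as pv
>>> deps = pv.fixture_dependence_table()          # 36 crops with DR classes
>>> records = pv.fixture_production_records()     # 2016 state-level CPVs
>>> rows, totals = pv.valuate(records, deps)
>>> totals.total_cpv_display, totals.total_psv_display
(2950519500, 983221475)
>>> pv.format_percent(totals.total_psv_exact / totals.total_cpv)
33
>>> pv.scenario_without(records, deps, ["Açaí"]).total_psv_display
347627425
>>> pct = pv.gdp_dependence_pct(298143775, 91838500, "Igarapé Miri")
>>> pv.format_pct_2dp(pct), pv.band(pct)
(Decimal('324.64'), 'above_50')
```

Pollination services are worth US$983.2 million — one third of the state's
US$2.95 billion crop production. Removing açaí alone drops PSV to US$347.6
million, and in Igarapé-Miri the service value is 3.2× the municipality's
recorded GDP (informally traded açaí is absent from GDP).

The same operations are available from a shell:

```bash
pollival synth --seed 1 --out-dir data/          # synthetic dataset + ground truth
pollival dependence --production data/production.csv \
    --deps data/dependence_table.csv --gdp data/gdp.csv \
    --hierarchy data/hierarchy.csv --exclude-crop Açaí --out-dir reports/
pollival fixtures --out-dir fixtures/            # export the packaged study tables
```

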