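# Methods

## Model

The package implements the dependence-ratio method for valuing crop
pollination. Each crop's pollination service value is

    PSV = CPV × DR

with CPV the annual market value of production (US$) and DR the fraction of
that production attributable to animal pollinators. DR is not estimated
here; it is assigned through categorical dependence classes, each a closed
percentage interval whose arithmetic midpoint (as a fraction) is the class
DR:

| class     | interval (%) | DR   |
|-----------|--------------|------|
| essential | 90–100       | 0.95 |
| high      | 40–90        | 0.65 |
| modest    | 10–40        | 0.25 |
| little    | 0–10         | 0.05 |
| none      | 0            | 0    |
| unknown   | —            | —    |

"Great" is accepted as an alias of "high" and "no increase" of "none",
because published tables use both spellings. A percentage that falls
exactly on an interval boundary (10, 40, 90) is assigned to the *higher*
class; the source intervals overlap at their bounds and give no rule, so
this convention is ours, documented and deterministic.

`unknown` is deliberately distinct from `none`: a crop with no dependence
data keeps its CPV in production totals but contributes *nothing* (not
zero) to PSV. Zeroing it would understate uncertainty; dropping its CPV
would corrupt production totals.

The method's assumptions are those of the dependence-ratio literature:
DR is constant across cultivars, regions and years; pollinator loss is
total and instantaneous in counterfactuals; no price response (producer
prices fixed, no consumer-surplus or elasticity adjustment); and the
published class midpoint is an adequate point estimate of DR.

## Monetary arithmetic and rounding

All money travels as `decimal.Decimal`. This matters because CPVs in the
source data are multiples of US$250 and DRs are multiples of 0.05, so exact
half-dollar products (x.5) are common; binary floats would round them
unpredictably. Two conventions are load-bearing:

- **Display rounding is half-away-from-zero** to whole dollars. This is
  established empirically from published rows whose exact PSV ends in .5
  (soybean 98,436,312.5 → 98,436,313; melon 14,487.5 → 14,488); banker's
  rounding would fail them.
- **Aggregate-then-round.** Totals are summed over unrounded products and
  rounded once at the end. On the packaged state table, ten of the twenty
  pollinator-dependent crops have exact PSVs ending in .5, so the sum of
  the display-rounded rows exceeds the display-rounded total by exactly
  $5 — a reconciliation identity the test suite checks by brute force.

Dependence percentages are formatted to two decimals (half-away-from-zero)
for reports, but banding always uses the unrounded value.

## Spatial aggregation

Valuation rows roll up a municipality → microregion → state partition at
full precision, so totals are conserved exactly at every level (checked on
100 random synthetic datasets). Municipalities with no production are
retained with zero totals, so municipality counts survive aggregation. A
region's main crop is the one with the largest CPV; ties break
lexicographically on the normalised crop name — a deterministic convention
that real dollar-valued data never exercises.

Crop names are matched after trimming, casefolding and diacritic stripping
("Açaí" ≡ "acai"), with the original spelling preserved for output.

## GDP-dependence index

Per municipality, dependence = 100 × PSV / GDP, banded as: none (= 0),
below_1 (0–1), from_1_to_10 ([1, 10], both edges closed), above_10
((10, 50]) and above_50 (> 50). The closed [1, 10] interval is our
resolution of ambiguous prose bounds; it is consistent with a published
municipality at 10.16% being listed as "more than 10%". The index is
**not capped at 100**: where a dominant crop is traded informally its
production value is missing from GDP, and an index above 100% (Igarapé-Miri:
324.64%) is a legitimate, diagnostic output — flagged with a warning, never
truncated.

## Synthetic data generator

The study's per-municipality crop values are not redistributable, so the
generator emulates their structure with known ground truth. Defaults are
the study conditions where stated, and a single documented choice where
not:

| parameter            | default        | basis                                        |
|----------------------|----------------|----------------------------------------------|
| n_municipalities     | 144            | study region                                 |
| n_microregions       | 22             | study region (≥2 municipalities each)        |
| crop catalog         | 36 crops       | the packaged state table with its DR classes |
| production_scale     | lognormal(12.2, 2.0) log-US$ | heavy tail; median ~US$200k per crop-municipality, state totals the right order of magnitude |
| dominance_prob       | 0.09           | 13/144 municipalities with a >50% main crop  |
| dominance_share      | 0.97–0.99      | the "more than 97% açaí" municipalities      |
| zero_production_prob | 1/144          | one no-production municipality               |
| informal_fraction    | 0.5            | informal açaí trade absent from GDP          |
| gdp_base             | lognormal(18.4, 1.0) log-US$ | median ~US$100M non-agricultural GDP |

Crop counts per municipality are uniform on 1–23, the observed range; the
true joint distribution is unpublished and not modelled. Recorded GDP is
non-agricultural base + CPV − the informal fraction of the dominant crop's
value, which reproduces the above-100% dependence pathology when the
informal fraction is high.

Ground truth (per-region CPV/PSV, GDP-dependence, main crops) is computed
inside the generator by a separate brute-force pass — plain dictionary
loops over the raw rows with its own DR literals, sharing no code with the
pipeline — so recovery tests are a genuine independent oracle, and recovery
is required to be *exact*, not approximate.

What the generator does **not** emulate: spatial autocorrelation, yield/area
structure, temporal dynamics, and the real covariance between crop mix and
GDP. Passing tests therefore demonstrate the pipeline's arithmetic and
accounting are correct on data of realistic shape; they say nothing about
DR validity or data quality in real applications.

## Problem sizes

Fixture-based checks run on the packaged tables (36 crops, 22 microregions,
13 municipalities) and complete in well under a second. Multi-seed
synthetic checks use down-scaled regions (16–30 municipalities, 4–6
microregions, 100 seeds for conservation; 20 datasets in the acceptance
script), chosen so the whole suite stays fast while exercising every code
path; generator correctness is size-independent because all checks are
exact identities.

## Known limitations

- The packaged microregion table is used as published; its column sums
  differ from the state table's totals by ~0.09% (an inconsistency internal
  to the source tables), so microregion rows are fixture inputs, never
  recomputed from crop-level data.
- The shipped hierarchy file covers the 22 microregions and the 13
  highly dependent municipalities only; full-scale hierarchies are
  generated synthetically.
- Integer-percent share formatting is nearest-integer; source prose that
  truncates ("about 64%") can differ by one point from this convention.
- No currency conversion, inflation adjustment, price-quantity
  decomposition or consumer-surplus metrics: the valuation is gross revenue
  attribution only.
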