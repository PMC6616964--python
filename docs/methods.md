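# Methods

This note documents the data model, the three classification
procedures, the comparison statistics, the synthetic-data generator,
and the numerical and design choices behind them.

## Data model

The unit of analysis is the census tract, observed at a small set of
calendar years (typically 1990, 2000, 2010, 2013 — decennial census
plus American Community Survey 5-year vintages).  Per tract-year the
panel carries: population; median household income (USD/yr); median
home sale price (USD); % adults 25+ with a bachelor's degree; %
low-income households; % housing built in the prior 20 years; % urban
census blocks; % renter households; % non-white population; and a
college-town flag.

Conventions that matter:

* **Percent variables live on the 0–100 scale everywhere.**  Files
  carrying fractions are rejected, not rescaled: silent rescaling is
  the classic corruption path for socioeconomic tables, and a tract
  with "0.43" college share is representable (0.43%), so the ambiguity
  cannot be resolved automatically.
* **Missing is missing.**  Absent cells become `None`, never zero, and
  each consumer decides its own missing-data behavior explicitly
  (regional medians skip missing tracts; Freeman excludes with a
  logged `MISSING_DATA` reason; Landis and the UDP tree emit
  `UNCLASSIFIED_MISSING`, which is always reported separately and
  never folded into a substantive category).
* **Monetary values are nominal.**  No deflator is applied by default;
  whether to inflation-adjust is an analysis decision the caller makes
  by transforming the panel before classification.  Note that the
  Landis classifier is entirely rank-based and therefore indifferent
  to any common-year deflator.

Two region-level reference statistics feed the classifiers, both
computable from the panel alone:

* *Regional median income* is the median across tracts of tract median
  household income.  A true region-wide household median is not
  recoverable from tract medians; the tract-level median is the
  closest well-defined operationalization and is used consistently.
* *Regional education change* is the population-weighted mean of tract
  percentage-point changes in college share (weights: tract population
  at the window end).  Weighting is configurable to unweighted; the
  weighted form is the closest computable proxy for "the region as a
  whole" when the 25+ denominator populations are not in the panel.

## Freeman classifier

Eligibility at the baseline year uses inclusive comparisons ("at or
below" the medians, "at least" 50% urban); the gentrification test
uses strict ones (a price *increase*, education growth *exceeding* the
region).  These boundary semantics are unit-tested, since tracts do
land exactly on regional medians.

Exclusion reasons are assigned sequentially — income, then urbanicity,
then housing age — so a tract failing several criteria is counted once
under the first.  This makes regional exclusion decompositions sum
exactly to the excluded total, which is the accounting convention used
in regional studies and is enforced as an invariant.

Defaults: baseline 2000, gentrification window 2010–2013, urban
threshold 50%.  The window is configurable (2000–2013 is the other
natural choice when aligning with decade-scale demographic tables);
education change is percentage points by default, relative percent by
option.

## Landis classifier

Deciles are assigned within region at each year from average
(mid) ranks, `decile = min(10, 1 + floor(10(r−1)/n))`, so tied incomes
always share a decile and no label depends on tract ordering.  With
`n` distinct values each decile receives between `floor(n/10)` and
`ceil(n/10)` tracts (property-tested).  Defaults: baseline 1990, end
2013, gentrifying = start in deciles 1–4 and rise ≥ 2, declining =
start in deciles 7–10 ("top four", ascending-income convention with
1 = poorest) and fall ≥ 2.  The classifier is invariant under any
strictly monotone transformation of incomes within a year.

## UDP-style typology

The Urban Displacement Project's Regional Early Warning System
estimates displacement typologies from a mix of census, home-sales,
business and transit data, some of it proprietary.  That estimation is
not reproducible from a public tract panel, so this package offers:

1. **Verbatim ingest** of an official typology table (CSV with a
   9-code vocabulary: `LI_EARLY`, `LI_AT_RISK`, `LI_UNDERGOING`,
   `LI_ADVANCED`, `MHI_EARLY`, `MHI_AT_RISK`, `MHI_UNDERGOING`,
   `MHI_ADV_EXCLUSION`, `COLLEGE_TOWN`), provenance-tagged
   `rews_ingest`.
2. **A simplified three-signal rule tree**, provenance-tagged
   `simplified_rule_tree`, which must not be read as a REWS
   replication.  Stratum: low income iff low-income-household share
   strictly > 39% (evaluated at the window end by default; the exact
   39.0% boundary falls to mid/high income because the low-income
   definition is strict).  Signals over the window: `losing_li` (share
   decline > 0 pp, strict), `market_hot` (price appreciation ≥
   regional median), `demo_shift` (college-share pp growth ≥ regional
   median).  Stages: losing ∧ shifting → advanced (labelled "advanced
   exclusion" in the mid/high stratum); losing alone → undergoing;
   hot market without loss → at risk; otherwise early.  The
   college-town flag overrides everything, as an input (the official
   college-town criteria are not reproduced here).

The tree deliberately omits REWS inputs a tract panel cannot support
(prewar building share, jobs/transit proximity, market-rate
development).  Raising the loss threshold can only demote tracts from
the displacement stages toward early/at-risk (monotonicity, tested).
The full (stratum × signals × flag) truth table is fixed and tested
exhaustively.

## Comparison statistics

Category shares, cross-tabulations and per-category summaries are
descriptive only; no inferential statistics are attached because the
inputs are complete enumerations of a region's tracts, not samples.

* All printed percentages are rounded half-up to one decimal in a
  single routine; raw values are always retained.  Sums of
  independently rounded shares can differ from the share of the summed
  counts by a few tenths (e.g. five category shares rounding to a sum
  of 46.7 while the pooled count gives 46.6); reporting raw values
  alongside makes such drift visible instead of silently matching
  either convention.
* Cross-tabs are computed over the tract-id intersection of two label
  sets, with column percentages (cell / column total).  Tracts present
  in only one set are counted and reported, never dropped.
* Per-category summaries aggregate income as the median across tracts
  (configurable to mean) and percent variables as unweighted means;
  change columns are relative percent changes of the category-level
  aggregate (configurable to percentage points, or to means of
  tract-level changes).  The aggregation choice is configurable
  precisely because published tables rarely state theirs.

## Synthetic region generator

The generator emulates a Bay-Area-scale metro region — default 1,500
tracts, years (1990, 2000, 2010, 2013), baseline incomes log-symmetric
around a regional median of $79,671, college share centered near 43%,
~90% of tracts urban — with four planted change regimes:

| regime | weight | income | edu (pp) | price | LI share (pp) |
|---|---|---|---|---|---|
| STABLE | 0.87 | −7% | +2 | 0% | +1 |
| GENTRIFYING | 0.06 | +42% | +15 | +50% | −8 |
| DECLINING | 0.04 | −35% | +1 | −15% | +6 |
| HOT_MARKET_NO_LOSS | 0.03 | +5% | +2 | +45% | +1 |

Drift magnitudes are directional caricatures of a
gentrifying-vs-declining contrast at a realistic scale; mixture
weights reflect that the vast majority of metro tracts are stable
over a 13-year window.  Baseline cross-sections enforce the expected
correlations (income negatively associated with low-income and renter
shares, positively with education); gentrifying tracts draw low
incomes, old housing stock and high urbanicity so they are
gentrifiable by construction; 2010 values are linear interpolations of
the 2000→2013 drift; 1990 is a mild rank-preserving backcast.

Noise is independent Gaussian perturbation of each drift
(`noise_sd` in units of 10% for relative drifts, 3 pp for
percentage-point drifts), with results clipped into valid ranges and
clipping logged.  At `noise_sd = 0` drifts are exact, which makes
planted-truth recovery tests sharp: Freeman recovers exactly the
eligible gentrifying-regime tracts, `plant_decile_jumpers` constructs
panels where Landis recovers exactly the planted jumper set, and the
UDP tree reproduces the planted signal combinations.  One degeneracy
is deliberate and documented: the stable regime sits *at* the regional
median for the market and demographic references, so its `≥`-signals
are knife-edge by construction; recovery tests therefore assert
exactness for the well-separated regimes and use drift values that
make the references exact (0.0) where stable-tract signals matter.

What the generator does **not** emulate: spatial autocorrelation (the
polygons are a synthetic square grid near (−122.5, 37.0), labelled as
such), measurement error correlated across variables, tract boundary
changes between census vintages, and missingness patterns of real ACS
tables.  Passing recovery tests therefore demonstrate correctness of
the classification logic, not performance on real census extracts.

## Numerical choices

* Decile arithmetic `floor(10(r−1)/n)` is exact in floating point for
  the integer and half-integer mid-ranks that occur (products stay far
  below 2⁵³), so no epsilon is needed.
* Panel CSVs order rows by (tract_id, year) and print floats via
  `repr`, making writes byte-deterministic and read-write round-trips
  exact.  GeoJSON output sorts features and keys for the same reason.
* Percentage rounding is half-up (`Decimal`), not banker's, matching
  how tables are conventionally printed.
* Degenerate inputs: empty panels write header-only CSVs; empty
  categories produce `n_tracts = 0` summary rows; an all-missing
  variable is an error naming the variable; a denominator smaller than
  the labeled count is an error rather than a >100% share.

## Scope and limitations

* Exclusion-reason attribution is order-dependent by design; a tract
  failing income and urbanicity is counted under income only.
* The simplified UDP tree is a stand-in with honest provenance
  labelling; quantitative stage cut-offs beyond the three signals are
  not modelled.
* No tract-boundary crosswalks, no download/harmonization of census
  products, no cartographic rendering (the contract ends at valid,
  typology-annotated GeoJSON), no health-outcome modelling.
* Problem sizes used in the test and acceptance runs (panels of
  60–300 tracts, 1,000-vector decile property sweeps, 5-seed recovery
  batches) were chosen as the smallest scales at which every property
  is non-trivially exercised; the generator defaults remain at the
  1,500-tract regional scale.
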