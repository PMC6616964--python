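# tractchange

Classify census tracts by gentrification and displacement status, and
compare the classifications.

`tractchange` is for researchers in urban epidemiology, public health
and housing policy who need neighborhood-change exposure measures from
longitudinal tract-level socioeconomic tables.  It implements three
widely used classification procedures over the same panel data model,
plus the machinery to compare them — because the three procedures can
disagree dramatically about *which* neighborhoods are gentrifying, and
robust studies need to check their findings against more than one
measure.

## The three classifiers

**Modified Freeman method** (`tractchange.freeman`).  A tract is
*gentrifiable* at a baseline year `t0` if

1. its median household income ≤ the regional median tract income,
2. its share of housing built in the prior 20 years ≤ the regional
   median share, and
3. ≥ 50% of its census blocks are urban (replacing Freeman's original
   "central city" criterion).

A gentrifiable tract is *gentrifying* over a window `(t1, t2)` if its
median home sale price strictly increased and its percentage-point gain
in college-educated adults (25+) strictly exceeded the region's
population-weighted gain.  Excluded tracts carry the first failing
criterion as an exclusion reason (income → urbanicity → housing age),
so regional exclusion tallies decompose exactly.

**Landis 3-D method** (`tractchange.landis`).  Tracts are ranked into
within-region income deciles at a baseline and an end year, using
mid-rank ties:

```
decile(i) = min(10, 1 + floor(10 · (r_i − 1) / n))
```

A tract starting in deciles 1–4 that climbs ≥ 2 deciles is
*gentrifying*; one starting in deciles 7–10 that falls ≥ 2 deciles is
*declining*; everything else is *stable*.  Labels depend only on
relative rank: a uniform regional boom changes nothing.

**UDP-style displacement typology** (`tractchange.udp`).  Tracts are
stratified by low-income-household share (> 39% = low income, strictly)
and staged by three signals over a window — losing low-income
households, home-price appreciation ≥ the regional median ("hot
market"), and college-share growth ≥ the regional median.  The module
has two never-conflated paths: verbatim ingest of an official Regional
Early Warning System typology table, and a documented simplified rule
tree for self-contained analysis (see `docs/methods.md` for why the
full REWS estimation cannot be reproduced from a public tract panel).

## Worked example

Generate a 300-tract synthetic region with planted change regimes, run
all three classifiers, and cross-tabulate:

```
$ tractchange simulate --n-tracts 300 --seed 11 --out-dir demo
$ tractchange classify --panel demo/panel.csv \
    --method freeman --method landis --method udp --out-dir demo/out
$ tractchange compare --labels demo/out/freeman_labels.csv \
    --labels demo/out/landis_labels.csv --out-dir demo/cmp
```

`demo/out/category_shares.json` then contains (excerpt):

```json
"freeman": {
  "counts": {"EXCLUDED": 225, "GENTRIFYING": 23, "NOT_GENTRIFYING": 52},
  "shares_pct": {"EXCLUDED": 75.0, "GENTRIFYING": 7.7, "NOT_GENTRIFYING": 17.3}
},
"landis": {
  "counts": {"DECLINING": 3, "GENTRIFYING": 19, "STABLE": 278},
  "shares_pct": {"DECLINING": 1.0, "GENTRIFYING": 6.3, "STABLE": 92.7}
},
"freeman_exclusions": {
  "excluded:MEDIUM_HIGH_INCOME": 150, "excluded:NOT_URBAN": 8,
  "excluded:HOUSING_TOO_NEW": 67
}
```

Of 300 tracts, Freeman deems 225 ineligible (150 above the regional
median income, 8 insufficiently urban, 67 with too-new housing —
summing exactly to 225) and flags 23 as gentrifying; Landis flags 19.
The cross-tabulation shows how far the two measures agree:

```
$ head -5 demo/cmp/crosstab_freeman_labels_x_landis_labels.csv
# counts: rows=freeman_labels cols=landis_labels
freeman_labels,DECLINING,GENTRIFYING,STABLE
EXCLUDED,3,1,221
GENTRIFYING,0,18,5
NOT_GENTRIFYING,0,0,52
```

18 of Freeman's 23 gentrifying tracts are also gentrifying under
Landis here; on real regional data the overlap is typically far
smaller, which is the point of computing it.

All of this is equally available as library calls
(`freeman_run`, `landis_run`, `udp_run`, `crosstab`,
`category_shares`, `summarize_by_category`, `export_geojson`), and
`tractchange export-geojson` writes a typology-annotated GeoJSON
FeatureCollection for mapping in any GIS tool.

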