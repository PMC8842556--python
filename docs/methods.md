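# Methods

This note documents the models, rules and design choices behind `rhcp`, the
way they are actually implemented, so that a user can judge what the numbers
in a generated profile mean and what the test suite does and does not show.

## The profile pipeline

A regional health care profile answers one request: a **location
municipality**, a **maximum car-travel time** (default levels 10, 15 and 20
minutes) and an optional **comparator district**. The pipeline runs in five
stages:

1. **Catchment extraction.** Travel time between municipalities is the
   shortest path on a weighted undirected graph (nodes: municipalities;
   edge weights: car-travel minutes between neighbouring municipalities,
   centroid to centroid). The catchment is the isochrone membership set —
   every municipality whose travel time from the location is at most the
   cutoff. The boundary is closed (time = cutoff is inside). Catchments
   deliberately ignore district borders: they approximate the clientele of
   a primary health care unit, not administrative geography. Unreachable
   municipalities are simply excluded; a disconnected network is legal
   input.
2. **Aggregation.** Each of the 35 indicators declares how municipal raw
   values combine over a region (catchment, district, or nation):
   * *mean* — unweighted arithmetic mean of member municipal values. This
     is the default reading of "averages of all municipalities";
     population-weighted averaging exists behind a switch
     (`population_weighted`) but is off by default, so small and large
     municipalities count equally.
   * *sum* — regional total (population, facility counts).
   * *ratio of sums* — Σ numerator / Σ denominator × `scale_per`,
     recomputed from regional totals rather than averaging municipal
     ratios. This keeps "inhabitants per GP"-type indicators well defined
     in municipalities with zero providers, and makes the singleton region
     equal the municipality's own ratio. A zero regional denominator yields
     the missing marker (NaN), rendered as "n/a".
   * *nearest facility time* — travel time from the location municipality
     to the nearest municipality hosting the facility type (0 if the
     location hosts one). Districts and the nation have no distinguished
     location, so their reference value is the unweighted mean of their
     members' nearest-facility times.
3. **Outlier cleaning.** The district value set of each indicator is
   winsorised at Tukey fences before any distribution statistics: with Q1,
   Q3 the quartiles and IQR = Q3 − Q1, values outside
   [Q1 − k·IQR, Q3 + k·IQR] are set to the fence (multiplier k = 3.0,
   configurable). Winsorisation, not deletion, so no district disappears
   from the comparison; the operation is idempotent, and an audit trail of
   altered values accompanies every profile. Catchment values are never
   winsorised — the local value must stay authentic. Missing district
   values pass through untouched and do not influence the fences.
4. **Distribution and rank.** The cleaned district values give the
   five-number summary shown in the boxplots: minimum, 25th percentile,
   median, 75th percentile, maximum (whiskers span the total range). All
   quantiles use linear interpolation between closest order statistics
   (the "type 7" convention, fixed and documented because quantile
   conventions differ across ecosystems). The catchment is then inserted
   among the district values; rank 1 is the most favourable position under
   the indicator's polarity (highest for `higher_better` and `neutral`,
   lowest for `lower_better`), with ties taking the best rank. Polarity
   drives rank direction only; it never alters values. The national
   reference value is computed over all municipalities by the same
   aggregation rules (mean: unweighted mean; sum/ratio: national totals).
   The comparator district's displayed value is its cleaned value — the
   same number that positions it inside the displayed distribution.
5. **Rendering.** The report is a ≥ 5-page A4 PDF: a map page (catchment
   ochre, location black dot, comparator district green), the 35-indicator
   boxplot panel grouped under the five domain headings (red line =
   national value, circle = catchment value, square = comparator value),
   the tabular results with absolute counts, and two pages of indicator
   definitions. The page-3 table is also written as a sidecar CSV at full
   precision; display rounding (percentages to one decimal, counts and
   minutes to integers) happens only in the PDF layer. Rendering is a pure
   view and, with a frozen timestamp, byte-reproducible. Since the
   synthetic country has no real municipal boundaries, the map uses
   Voronoi cells of the municipality points clipped to the bounding box as
   stand-in polygons.

The batch counterpart (`generate_all_datapoints`) computes the aggregated
catchment value for every (municipality, cutoff, indicator) combination in
one pass, reusing a single shortest-path tree per municipality across all
cutoffs and indicators. Undefined values are kept as empty cells, so the
row count is exactly n_municipalities × n_cutoffs × n_indicators (2122 × 3
× 35 at the national default; 6366 rows per indicator). Batch rows are
exactly equal — bit for bit — to the corresponding single-request values,
because both paths pull member values in the same canonical (sorted-id)
order and share the same cached nearest-facility-time maps.

## The indicator catalogue

The default catalogue holds 35 indicators in five domains (demography and
socio-economics: 6; disease prevention and risk factors: 4; epidemiology
and mortality: 12; health care service supply: 9; outpatient care
utilisation: 4). Each entry carries the aggregation kind, raw-value column
names, units, polarity, reporting scale, and two data-limitation flags:

* `source_granularity = supra_municipal` marks the eight indicators whose
  values are only available above municipality level and are interpolated
  downwards. The choice of which eight — the four prevention/risk-factor
  items plus the four survey-derived prevalences (type-2 diabetes, mental
  disorders, musculoskeletal disorders, chronic head-/neck-/backaches) —
  is an editorial assumption: these are the health-survey items in the
  catalogue, and survey data are the typical source of such interpolation.
  The flag records the limitation; no interpolation method is claimed or
  reproduced.
* `linkage_flag` marks the four inpatient-rate indicators ("rate of
  inpatients with … within 2 years") that require person-level record
  linkage across hospital episodes in the original data system. Computing
  such rates from episode records is out of scope here; the flag is
  metadata only.

Aggregation kinds were assigned by the quantity's semantics: percentages,
prevalences, rates and life expectancies average (mean); population and
facility counts total (sum); "X per Y" indicators recompute from regional
totals (ratio of sums); "distance to the nearest …" indicators are
travel times. Indicator ids are invented stable snake-case tokens (the
source material provides display labels only). Polarities are set
editorially (life expectancy `higher_better`, smoking `lower_better`,
population `neutral`, …) and affect only rank direction.

## The synthetic country generator

There is no public accession for the real inputs (the original system runs
on more than ten restricted national data sources), so the package ships a
seeded generator that emulates the country's *structure* at full scale.
Its defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| municipalities / districts | 2122 / 116 | the national scale |
| area per municipality | 40 km² | ≈ 84 000 km² country at full scale; density kept constant when scaled down |
| road graph | 4-nearest-neighbour + connectivity augmentation | sparse inter-municipal road network |
| edge minutes | Euclidean km at 60 km/h × exp(N(0, 0.15)) | car travel with road-quality noise |
| populations | log-normal, median 2000, σ = 1 | right-skewed municipal sizes, ≈ 7–9 M national total |
| age bands | multinomial around (14.5 %, 65.5 %, 10.5 %, 9.5 %) with Dirichlet jitter | bands sum exactly to the total |
| facilities | Poisson(population × rate); hospitals Bernoulli(1 − e^(−pop/40 000)) | placement probability increasing in population; national counts of plausible magnitude (≈ 1 GP per 1800, ≈ 1 pharmacy per 6000 inhabitants, …) |
| indicator fields | Gaussian field with exp(−d/50 km) correlation, shifted/scaled/clipped per field | nearby municipalities resemble each other |

Field-level targets (e.g. smoking ≈ 21 ± 3 %, male life expectancy ≈
79.5 ± 1.2 years) are plausible central European magnitudes; the fixture
is fictive by construction and not calibrated to any real distribution.
Supra-municipal fields are generated by averaging the municipal field per
district and copying the value to all members — emulating the blurring
that interpolation from higher regional levels causes in real profiles.
If a facility type ends up absent countrywide (possible only in very small
scaled-down fixtures), one facility is placed in the largest municipality
so every national indicator stays defined.

Randomness: one root seed is split into named child streams (coordinates,
populations, age structure, network noise, facilities, fields,
equivalents) so that the pipeline is deterministic given (seed, params)
and generation steps cannot silently perturb each other. District
assignment is planar k-means on the coordinates (clusters relabelled west
to east), which yields contiguous, non-empty districts of comparable
population magnitude.

What passing tests on this fixture show — and what they do not: they
validate the computational pipeline (graph algorithms, aggregation rules,
cleaning, ranking, rendering) end to end at the real problem size. They
do not validate the plausibility of any real indicator value, real road
travel times, or the behaviour of the interpolation used for survey
indicators in the original system.

## Numerical choices and degenerate inputs

* Shortest paths: Dijkstra (positive weights enforced at graph
  construction). The test suite cross-checks against an independent
  exhaustive-relaxation all-pairs oracle on random networks with integer
  minute weights, where both algorithms must agree exactly.
* Quantiles: NumPy's type-7 linear interpolation everywhere; the oracle in
  the tests is an independently written sort-and-interpolate rule.
* Missing values: NaN is the single missing marker throughout (unreachable
  facility, zero ratio denominator); reports render it as "n/a", the batch
  table as an empty cell, and ranks become missing rather than fabricated.
* Constant district values: IQR = 0, both fences equal the common value,
  nothing is flagged. Single-element inputs are legal for cleaning
  (unchanged) but a distribution summary requires at least two non-missing
  district values.
* Tie-breaks in ranking: the catchment takes the best rank among equals
  (rank = 1 + number of strictly better values).
* Fixture serialization uses `%.17g` floats and round-trip parsing, so
  write → read reproduces the fixture bit for bit.

## Problem sizes used in the test suite

Unit tests run on a 60-municipality / 8-district fixture; the catchment
nesting and report-integrity checks use 300 municipalities / 20 districts;
the structural-count and batch-agreement checks run at the full national
scale (2122 / 116, all three cutoffs). These sizes keep the default suite
around half a minute while still exercising the full-scale path once.

## Known limitations

* Travel times live on an abstract inter-municipality graph: no real road
  routing, speed profiles, turn restrictions, or public-transport
  accessibility.
* Raw indicator values are inputs; computing them from claims or
  hospital-episode records (including the four record-linkage rates) is
  out of scope.
* The outlier rule (Tukey fences, k = 3, winsorisation, applied to the
  district set only) is this package's own definition of "automatic
  cleaning of outliers"; other reasonable rules exist.
* The map page's Voronoi cells are a visual stand-in, not administrative
  boundaries.
* Interactive on-screen overlays of the original reporting tool are
  replaced by static content; the PDF is the sole output medium.
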