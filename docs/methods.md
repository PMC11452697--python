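# Methods

This note records how `envlink` models the event-environment linkage,
the parameters that matter, and the design choices made where more than
one defensible convention exists. It documents behaviour; every number
quoted is computed by the test suite or `scripts/acceptance.py`, not
asserted here.

## Data model

All coordinates are WGS84 longitude/latitude, in that order (the
GeoSPARQL CRS84 convention), everywhere — files, in-memory containers,
WKT literals. All dates are calendar dates: the linkage operates at
daily resolution, and sub-daily inputs are rejected at read time rather
than resampled, because resampling is a modelling decision the user
should make explicitly upstream.

Gridded datasets store axis values as **cell origins**: cell (i, j) is
the half-open rectangle `[lon_j, lon_j+Δ) × [lat_i, lat_i+Δ)`, so every
point — including one exactly on a cell boundary — maps to exactly one
cell. Axis spacing must be regular to within 1e-9°.

Missing values (NetCDF fill values/NaN, empty tabular cells) map to one
internal flag (NaN) and are carried, never dropped: coverage accounting
downstream needs to see them. The `.grid` extension is read as the
tab-separated station dialect with the fixed header
`station_id lon lat date variable value`.

## Exposure window

`temporal_window(t, L, W)` covers the dates `d` with
`t − L − W ≤ d < t − L` — a half-open span of exactly `W` dates ending
`L` days before the event, with the event day always excluded. The
exclusion is deliberate: including the event day would let same-day
observations (which in many registries are recorded *after* the event)
leak into the exposure, a reverse-causation hazard. Defaults are
`lag_days=0`, `window_days=7`; both are study-specific and should be
set per analysis, typically from the biology of the hypothesised
exposure-response delay.

## Spatial assignment

- **nearest_station / buffer** use great-circle (haversine) distance on
  the WGS84 sphere (R = 6371.0088 km).
- **proximity_polygon** builds a planar Voronoi (Thiessen) diagram in
  an equirectangular projection centred on the station centroid
  (x = Δlon·cos φ₀, y = Δlat). Cell membership then equals
  nearest-station under that planar metric, which the tests assert
  against a brute-force oracle. The planar and great-circle routes can
  disagree near cell edges at continental scales; for the
  sub-10°-extent use cases targeted here the difference is negligible,
  and the equivalence property is only claimed in the planar metric.
- **area_contains** selects the most specific (smallest-area)
  administrative polygon covering the event point, or the polygon named
  by an area-coded event, then expands it to the stations inside it or
  the grid cells whose origins fall inside it. Containment counts
  boundary points as inside. No areal weighting of partially
  intersected grid cells is applied — cell-origin membership is
  deterministic and assumption-free, at the cost of a discretization
  error of at most one cell width at the area boundary.
- Grid datasets under the three point methods resolve to the single
  half-open cell containing the point.
- Every tie (equidistant stations, boundary-shared Voronoi edges)
  resolves to the lexicographically smallest source id, so runs are
  reproducible to the byte.

An event with no context (point outside every area, empty buffer) is a
*skip-log entry with a reason code* (`no_spatial_context`,
`window_outside_coverage`, `no_observations_in_window`), never an
error: skipped events are data about coverage, not failures.

## Semantic uplift

Each dataset becomes an RDF Data Cube dataset. One observation node per
(location, date, variable) with a non-missing value carries exactly
five triples: `rdf:type qb:Observation`, `qb:dataSet`, the time
dimension (`sdmx-dimension:refPeriod`, `xsd:date`), the location
dimension (`sdmx-dimension:refArea`, the source IRI) and one measure
literal (`xsd:decimal`). Multi-variable datasets therefore expand to
one node per variable — the simplest Data Cube shape, and one that
makes the 5-triples-per-observation law mechanically testable.
Structural triples define the DSD, component specifications, measure
properties (with units as `sdmx-attribute:unitMeasure`) and source
geometries as CRS84 WKT literals. The SDMX-RDF companion dimensions
are reused rather than minting per-run dimension IRIs so the query
template is independent of the configured base IRI.

Numeric literals are serialized positionally with the shortest
representation that parses back to the identical float (xsd:decimal
forbids exponent notation), which is what makes the
graph-to-table round-trip exact rather than approximate.

The uplift is a direct programmatic mapping to this target shape; no
mapping language is interpreted. Serialization is canonical — sorted
triples, fixed prefix table, one triple per line — so equal graphs
always produce byte-identical Turtle.

### Metadata

Run metadata is a DCAT dataset record (title, licence, version,
temporal extent as a `dcterms:PeriodOfTime`, spatial extent as a WKT
bounding box, distribution URL), a PROV-O activity with `prov:used`
links to every input dataset, one `prov:generated` link to the output
and `prov:wasAssociatedWith` links to its agents (researcher → 
`prov:Person`, software → `prov:SoftwareAgent`, entity →
`prov:Organization`), and an ODRL policy. A missing licence is recorded
in the graph as an explicit open-rights statement, not raised as an
error: absent rights are a fact about the dataset worth publishing.

Provenance timestamps are *logical* — derived from the data's temporal
extent and the run seed — rather than wall-clock, so identical runs
export byte-identical graphs; the actual execution time lives in
`run_summary.json`.

## Graph-query backend

The SPARQL template binds an event IRI, a dataset IRI, a spatial
relation predicate and two `xsd:date` window bounds. Temporal selection
is genuine date-literal reasoning in the query engine. Spatial
selection is pre-materialized: the same spatial-assignment code that
drives the direct backend emits event→source link triples which the
query then consumes. This keeps the geospatial semantics in one
audited place (in-process SPARQL engines do not evaluate GeoSPARQL
topology functions) while preserving the meaningful contract, which is
asserted as a test: both backends return identical
(event, source, date, variable, value) multisets.

## Aggregation and export

Aggregation order is pinned: per-day mean over sources first, then the
temporal statistic over daily values. For nonlinear statistics
(min/max/sd) the opposite order gives different answers; fixing
spatial-first means "the maximum of the area-average daily level", the
usual exposure reading. `sd` uses the sample (n−1) denominator;
`count` counts distinct observed dates. Daily-level output emits one
record per observed window date as a one-day window with statistic
`daily_mean`.

Coverage = distinct observed window dates / window length. Records
below `min_coverage` are flagged; they are excluded from the CSV only
when `exclude_low_coverage` is set but always remain in the RDF graph
with a low-coverage quality annotation — the graph is the publication
artifact and should carry its own limitations. A variable expected
from a dataset but absent from an event's window still yields a
flagged coverage-0 record, so the analysis table's cardinality is
always events-with-context × variables × statistics.

The export triad is `linked_data.csv` (comma-separated, UTF-8, ISO
dates, fixed column order `event_id, dataset_id, variable,
window_start, window_end, agg, value, coverage, n_sources`),
`linked_data.ttl` (derived QB observations + metadata graph,
canonical), and a static self-contained `report.html` (inline styles,
no external assets, standing in for an interactive dashboard without a
server dependency), plus `skip_log.csv`.

## Synthetic data

The generator emulates the *shapes* of the real inputs the tool
targets: a gridded daily weather-like field, station pollution-like
series, nested administrative rectangles, and daily pseudonymous
events. Grids and stations share one value model,

    base_level + daily_amplitude·sin(2πt/365)
    + spatial_gradient·(lat − lat_south) + N(0, noise_sd),

with independent missingness at `missing_rate`, so grid-vs-station
comparisons of the same linkage are meaningful. Defaults describe a
small dense regional study: a 2°×2° extent, 120 days from 2021-01-01,
a 4×4 grid, 10 stations, 20 events, temperature (base 10 °C, seasonal
amplitude 8 °C, noise sd 1.5 °C, +0.5 °C/° north) and pm10 (base
20 µg/m³, amplitude 5, noise sd 3, −0.8/° north), no missingness.
Event dates keep a 60-day pre-event margin (auto-shrunk with a warning
for short series) so default windows fall inside coverage; event
locations are uniform in the extent.

Each generator draws from its own stream seeded by (seed, generator
name), so generators are pure functions of the spec and adding one
never perturbs another.

What the synthetic data does *not* emulate: spatial autocorrelation
beyond the linear gradient, weekday/holiday patterns, station outages
(missingness is i.i.d.), measurement bias, or realistic pollution
chemistry. Passing tests therefore demonstrate the correctness of the
linkage machinery — assignment, windows, aggregation, graph semantics,
determinism — not the epidemiological validity of any exposure derived
from real data.

## Problem sizes and numerical notes

The standard test configurations — 50 stations/200 events for the
Voronoi-vs-oracle check, 10 stations × 30 days × 2 variables (600
observations) for the uplift laws, 1000 draws for the window laws,
3 events × 2 variables for backend equivalence — are chosen to
exercise every code path while keeping the whole suite in seconds;
the generators scale to much larger configurations unchanged.

Degenerate inputs behave as documented: an empty dataset uplifts to
structural triples only; a zero-observation window yields a flagged
coverage-0 record; `sd` of a single day is missing (NaN); a zero-station
dataset is a configuration error. Grid spacing regularity is enforced
at 1e-9°; grid values must be finite or NaN.

## Known limitations

- One location per event: moving-address exposure histories must be
  encoded as multiple events per subject.
- No interpolation (kriging) between stations and no areal weighting of
  partially covered grid cells.
- The graph backend materializes spatial relations rather than
  evaluating GeoSPARQL topology functions in the query engine.
- The HTML report is static; interactivity is limited to what a single
  self-contained page provides.
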