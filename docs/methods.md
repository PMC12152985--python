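# Methods

This note documents the models implemented in `hmisaccess`, the parameter
defaults and why they were chosen, what the synthetic-region generator does
and does not emulate, and the numerical and design decisions a maintainer
should know about. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

The analysis operates on six routine service indicators — outpatient
attendance, malaria treatment, antenatal registration, facility births,
caesarean births, and first-dose pentavalent vaccination — reported yearly
per facility over 2016–2022. A facility *provides* a service in a year when
its aggregated count is strictly positive, and is *operational* in a year
when it provides at least one of the six indicators; with only these six
indicators available, "operational" is necessarily defined relative to them.
The provision cube is a complete boolean facility × year × indicator tensor
(an `xarray.DataArray`); rows absent from the record table are `False`.

Each indicator targets a population sub-group: outpatient and malaria care
the total population, antenatal/birth/caesarean care women of childbearing
age (15–49), and pentavalent-1 children under five. Caesarean sections
require hospital surgical capacity, so hospitals alone enter both numerator
and denominator of caesarean provision rates and are the only eligible
travel-time sources for that service.

## Coordinate QA

Published facility coordinates are checked against the polygon of the
facility's own district. Candidates are tried in a fixed order with
first-hit-wins semantics:

1. the point as published (→ `ok`);
2. the ordinate swap `(y, x)` (→ `repaired_swap`);
3. decimal shifts — ÷10 then ×10, applied to x alone, y alone, then both
   ordinates jointly (→ `repaired_decimal`);
4. if still outside but within a boundary tolerance (default **2,000 m**) of
   the district, the point is kept unchanged (`boundary_tolerated`) on the
   reading that the boundary, not the point, is inaccurate;
5. otherwise `unresolved`: the facility keeps its published coordinates, is
   retained for all temporal/classification analyses (which need no
   geometry), and is excluded only from travel-time sourcing, with a logged
   warning.

The swap-before-decimal order and the tolerance value are package choices;
no authoritative resolution order exists for these error kinds. A caveat
worth knowing: the joint ÷10 candidate maps the entire ×10-scaled
neighbourhood of the origin back into an origin-anchored district, so for
study areas whose working coordinates start near (0, 0) the decimal repair
is aggressive and `boundary_tolerated`/`unresolved` become rare. With
projected metric coordinates of realistic magnitude (hundreds of
kilometres), the candidates are discriminating. A gazetteer cross-check hook
is not implemented; the boundary-tolerance rule stands in for place-name
verification.

QA is idempotent: re-running it on its own corrected output yields only
`ok`/`boundary_tolerated`.

## Functional classification

Rules are applied to the 7-year operational vector in order, making the
classifier total:

- **no_service** — never operational;
- **closed** — operational in 2016, not in 2022;
- **newly_operational** — not operational in 2016, operational in 2022;
- **oscillating** — operational in neither endpoint year but in some year
  between;
- **other_intermittent** — operational at both endpoints with at least one
  non-operational year between. The five named groups are not exhaustive;
  this residual is reported separately rather than silently merged into
  *existing*;
- **existing_*** — operational every year, split on the indicator sets:
  *unchanged* if the set is identical in all seven years; *increased* /
  *decreased* if the 2022 set is strictly larger / smaller **in
  cardinality** than the 2016 set; *varying* otherwise. "Range of services"
  is read as the number of services; the edge case of equal-sized but
  different endpoint sets therefore falls into *varying* together with
  facilities whose intermediate years differ.

An exhaustive check over all 2⁷ operational patterns (in the test suite)
verifies that exactly one top-level class is assigned to every pattern.

## Fisher exact test

Ownership × functionality association is tested with an r×c Fisher exact
test written for this package (scipy covers only 2×2): the p-value is the
sum of probabilities of all fixed-margin tables no more probable than the
observed one under the multivariate hypergeometric null. Enumeration is
used when a cheap combinatorial bound (product of per-row composition
counts) stays below a cap (default 200,000 tables); otherwise a seeded
Monte-Carlo permutation estimate with a reported draw count (default
20,000) is returned, and the result object records which method ran.
Probabilities are compared in log space with a `1e-7` additive slack so
exact ties are counted despite float rounding; genuinely distinct
hypergeometric probabilities of small tables differ by far more than this.
Degenerate tables (an all-zero row or column) are rejected.

## Friction surface and travel time

Per-cell traversal cost (seconds per metre) is assembled with rasterisation
priority water < land cover < roads:

- walking speed by land-cover class, multiplied by the slope factor
  `e^{−3.5|s+0.05|}/e^{−3.5·0.05}` — Tobler's hiking function normalised to
  1 on flat ground so it *moderates* the land-cover speed rather than
  replacing it with the 6 km/h hiking baseline. Slope magnitude comes from
  DEM central differences and is treated isotropically, since travel
  direction along the eventual least-cost path is unknown when the surface
  is built;
- water cells are impassable (infinite cost) unless a road crosses them
  (bridges);
- road cells take their road-class speed with no slope adjustment
  (mechanised travel).

Default speeds are deliberately round placeholders a practitioner should
override with tracked-vehicle data for a real study area: walking 5 km/h on
open and built-up land, 2 km/h in dense vegetation; roads 80/50/20 km/h for
primary/secondary/tertiary classes.

Travel time to the nearest providing facility is the exact multi-source
shortest path on the 8-connected cell graph with step cost
`d(a,b)·(cost_a+cost_b)/2`, `d` = cell size orthogonally and √2·cell size
diagonally — the standard cost-distance discretisation, declared explicitly
so an independent oracle is well defined. The implementation builds the
sparse edge list and calls `scipy.sparse.csgraph.dijkstra` (multi-source,
`min_only`); the test suite compares it against a self-contained O(V²)
Dijkstra on random grids (agreement to 1e-9 minutes) and checks
monotonicity under added sources, exact linear scaling in the friction, and
the closed-form chamfer distance on uniform grids. Facilities on impassable
cells are snapped to the nearest passable cell within 500 m (default),
else dropped with a warning.

Band classification uses breaks {30, 60, 120} minutes with closed upper
bounds — [0,30], (30,60], (60,120], (120,∞) — so exactly 30.0 minutes counts
as "within 30 min"; unreachable cells fall in the last band. Change surfaces
(end − start) carry NaN plus explicit transition masks where reachability
changed, rather than signed infinities.

## Population projection

The baseline-year (2021) gridded population is projected with annual
geometric growth: forward `P_y = P_{y−1}(1 + r_y/100)`, backward by
division, compounded year by year (this also covers 2016–2017 for internal
consistency). The rate is a required input (scalar or per-year map; default
2.1 %/yr, a plausible national annual growth rate). Growth is spatially
uniform, so the spatial pattern, cell rank order, and sub-group extraction
all commute with projection exactly; a projection round trip is the identity
to float precision. Sub-group rasters multiply the projected total by the
year's census-derived proportion (defaults: women of childbearing age 0.24,
under-fives 0.13), applied uniformly in space because such proportions come
from census marginals, not per-cell data.

## Coverage

For each indicator and year, band populations are `bincount` sums of the
sub-group raster over the band raster — an exact partition, so band sums
equal the regional sub-group total and percentages sum to 100. Population
in cells outside every district (possible at synthetic edges) is included
in the totals. Indicator-years with no providing facility are logged and
skipped rather than fabricated. Facilities with unresolved coordinates
count in provision percentages but never as travel-time sources.

## Synthetic region generator

The generator emulates the statistical structure the analysis assumes, each
layer on its own independent random stream of a single seed:

- **terrain**: smoothed Gaussian-field DEM (0–300 m) and a three-class land
  cover (open / dense vegetation / built-up);
- **water**: a meandering north–south river polyline plus a lake polygon,
  forming a connected barrier (switchable);
- **roads**: a primary west–east trunk with secondary/tertiary branches to
  the north/south edges — connected, touching several region edges, and
  independent of the facility layer;
- **population**: Gaussian town-centre kernels over a light uniform
  background, normalised to the configured total (70,000 on the default
  20×20 km region, ≈175 persons/km²);
- **districts**: a rectangular partition (default 2×3);
- **facilities**: type mix 0.71/0.21/0.06/0.02
  (CHPS / health centre / hospital / maternity home) and ownership mix
  0.85/0.015/0.135 (government / faith-based / private), matching the kind
  of CHPS-dominated, publicly-owned facility network the analysis targets;
  true coordinates strictly inside a district. A configurable fraction
  (default 5 %) of *published* coordinates is corrupted — ordinate swap or a
  ×10 decimal shift of one ordinate — and the generator verifies against
  the QA candidate order that every injected corruption is uniquely
  repairable back to the truth, re-drawing the corruption kind otherwise.
  Repair round-trips are therefore exact *by construction*, which is what
  the recovery tests exercise;
- **service histories**: each facility draws a functional archetype
  (default mix: ~61 % unchanged-or-increased, 21 % newly operational, small
  closed/oscillating/no-service fractions) and realises it as a yearly
  prefix of its type's service pool in onboarding order — immunisation
  first, then outpatient + malaria, then antenatal, then birth, caesarean
  last and only in hospitals. This ordering gives the synthetic archive the
  expected correlation structure (outpatient ≈ malaria; antenatal ≥ birth).
  Hospitals floor their steady-state prefix at five of six services, since
  hospitals realistically offer nearly the full range and roughly half then
  provide surgical birth care in any steady year. Counts for provided
  services are Poisson, truncated to ≥1, with type-dependent means
  (hospital 2000 ≫ health centre 500 > CHPS 120 > maternity home 60) —
  magnitudes never matter downstream, only positivity.

What the generator does **not** emulate: real geography and road topology,
census microdata, per-cell demographic variation, month-level reporting
gaps, facility relocation, count misreporting other than full-year absence,
or spatially correlated coordinate errors. Passing tests therefore
demonstrate that the pipeline's logic is correct and internally consistent
under the stated assumptions — not that any particular real region has the
reported coverage levels.

## Problem sizes and determinism

Tests run the full pipeline at 200×200 cells with 150 facilities (the
scale the method targets at 100 m resolution for a sub-regional study) and
exercise component oracles at 20×20–60×60; the Fisher implementation is
checked exhaustively against an exact-fraction oracle over all 2×2 tables
with grand total ≤ 30 and all 2×3 tables with total ≤ 12, plus a seeded
sample of larger 2×3 tables. All generators, the Monte-Carlo Fisher
fallback, and the pipeline are seeded; outputs carry no timestamps, so
equal seed + config ⇒ byte-identical artifacts (checked via manifest
checksums).

## Known limitations

- No network (on-road graph) routing, congestion, seasonal road conditions,
  or monetary travel costs; travel is least-cost over the raster only.
- Cross-boundary service use is ignored: population is served only by
  facilities inside the study region.
- The functional classification is sensitive to the 2016 base year and to
  non-reporting (a facility that reported nothing is indistinguishable from
  one providing nothing).
- Decimal-shift repair near the coordinate origin is over-eager (see QA
  caveat above).
- The planar-metric grid assumes inputs were reprojected to a metric CRS
  and resampled to a common grid upstream.
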