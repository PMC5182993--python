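# Methods

This note documents the models, their assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Landscape representation

The landscape is a uniform grid of square cells (default 800 m ≈ 64 ha, the
quarter-section at which many prairie land-use decisions are made; cell
size is a config variable). A cell holds the *areas* (ha) of each landcover
class — natural: forest, grassland, shrub, water, and semi-natural tame
pasture; footprint: cropland, road, trail, cutblock, industrial, urban —
which must sum to the cell area (relative tolerance 1e-6). Sub-cell spatial
arrangement is discarded by design: the composition approach keeps small
but influential features (roads) without the cost of fine rasters. The
class taxonomy is user-overridable; unknown classes are rejected rather
than silently pooled. Cells outside the grid are absent neighbors (no
wraparound).

Forest is carried on **cohorts** (stand type × ecozone × age × area).
Because harvest moves area from the `forest` class to the `cutblock`
footprint class while the stand regenerates from age 0, cohorts partition
`forest + cutblock` area, not `forest` alone. The cutblock class is thus
simultaneously regenerating forest (for growth and carbon) and permanent
footprint (for the biodiversity index, which has no temporal recovery).

## Forest growth, carbon, and harvest

Volume and carbon curves are clamped polynomials of age: negative values
clamp to zero and the curve holds flat beyond `age_max`, because fitted
polynomials diverge outside their data range. The default library uses
smoothstep cubics rising to stratum-specific plateaus (e.g. spruce 400
m³/ha and 820 t CO₂e/ha in the Boreal Plains, × 0.85 in the Montane
Cordillera; carbon keeps a 40 t/ha below-ground floor at age 0). These
defaults have the right *shape* and order of magnitude; they are declared
placeholders — deployments supply fitted coefficients through config.

Harvest scheduling per mill-FMU-year:

1. Realized cut = AAC × a truncated-normal(mean 0.85, sd 0.08) fraction on
   [0, 1] (the full AAC is rarely cut; the distribution parameters are
   config since the historical record is jurisdiction-specific).
2. Eligible stands: cohorts with age ≥ 80 (config) and positive area.
3. Cells are taken in ascending transport cost until cumulative volume
   reaches the target, overshooting by at most the final cell (a selected
   cell is cut whole, so the overshoot is bounded by one cell). Ties break
   by ascending (row, col) — deterministic replay matters more than
   realism.
4. Clearcut removes all eligible volume; variable retention removes 25, 50
   or 75% chosen uniformly at random (intensity only, never spatial
   pattern, which cannot be represented at this cell size).

Transport cost is the least accumulated cost over the 8-connected grid
(Dijkstra), with the cost of a step equal to the traversal cost of the
*entered* cell's road class (paved 0.4 < unpaved 1.2 < low-speed corridor
2.5 < roadless 5.0 $/m³ per step, config), × √2 for diagonal moves. The
surface is static: mills do not re-plan roads as harvest proceeds.

Harvested cells are closed to re-entry for the rest of a simulation, in
both modes. This is the green-up/retention reading of variable retention:
volume retained in a cut cell is structure left on site, not an inventory
to return for next year. Without this rule the scheduler would repeatedly
harvest the cheapest cells' retained cohorts and variable retention would
paradoxically *concentrate* impact instead of spreading it.

Mill cash flow is volume × (conversion × product price − harvest/processing
cost − transport cost); NPV discounts cash flows at t = 1..T (t = 1
convention; rate default 2%). One mill per FMU; quota holders are not
separate agents.

## Water purification

One aggregate water year (no storm events, baseflow or groundwater),
matching the annual-coefficient formulation:

* **Runoff**: depth = precipitation × area-weighted runoff coefficient;
  volume scales by cell area.
* **Loading**: N, P, TSS loads = precipitation (mm) × Σ class area ×
  export coefficient (kg ha⁻¹ mm⁻¹), with separate coefficient tables for
  the three calibration region groups (Mountains; Foothills; pooled
  Boreal + Parkland + Grassland). Sediment = RUSLE, `A = R·K·LS·C·P` with
  C area-weighted over the cell's classes and R proportional to annual
  precipitation (0.5 per mm by default).
* **Routing**: the DEM is conditioned by priority-flood sink filling with
  an epsilon gradient (1e-6 m) across filled flats, which guarantees every
  interior cell a strictly lower D8 neighbor — so flat regions resolve
  deterministically and routing can never cycle. D8 ties break by the
  fixed neighbor order E, SE, S, SW, W, NW, N, NE. The river network is
  the set of cells with flow accumulation ≥ a config threshold (a
  stream-initiation choice; no universal value exists).
* **Retention**: a parcel's loads attenuate multiplicatively at each
  transit cell strictly between origin and river entry, by the cell's
  area-weighted retention fraction per substance (sediment defaults to
  1.5 × the nutrient values, capped at 1 — retention is substance-specific
  with a shared default). Water volume is conserved; there is no in-stream
  retention or decay.
* **Edge outlets**: parcels whose path leaves the grid before meeting a
  river deliver to an implicit edge outlet. "Supplied" counts delivery to
  the stream system including these outlets (tallied separately), so per
  substance Σ loading = Σ supplied + Σ retained holds exactly.

The default runoff/export/retention tables are order-of-magnitude
placeholders anchored on phosphorus (~0.1 kg ha⁻¹ yr⁻¹ from forest to
~0.8 from cropland at 450 mm), N ≈ 10 × P and TSS ≈ 300 × P, with the
mountain and foothill groups scaled to 0.6 and 0.8 of the plains values.
They carry the right ordering (cropland > pasture > natural; retention the
reverse) and are meant to be replaced by calibration.

**Calibration** is global: each candidate export-coefficient set (e.g. 10
Latin Hypercube samples) is run through a full water year, and the set
minimizing the RMSE of cumulative annual load at a region group's gauges is
selected independently per group. RMSE over monitoring points is a declared
choice of objective; any loss over the monitoring table could be
substituted.

## Pollination

Ground-nesting wild bees dominate regional pollination; annual cropland
provides no nesting habitat. Nesting habitat for a field is the natural +
pasture area within the foraging radius by **centroid distance**, focal
cell included (the 750-m field buffer cannot be resolved below an 800-m
cell, so at default settings the neighborhood is the focal cell; at radius
≥ 800 m the rook neighbors join). Bee abundance is Michaelis–Menten in
habitat (half-saturation 150 ha of the ~320 ha reachable at radius 850 m),
and per-hectare yield uplift is Michaelis–Menten in abundance (asymptote
0.46 t/ha ≈ 30% of the 1.54 t/ha baseline yield — the share of canola
revenue attributable to pollinators). Both functional forms are pluggable;
the field relationships they stand in for are survey-fitted and belong in
config, which is why the tests of this module are property-based
(zero-at-zero, monotone, saturating) rather than coefficient-based.

Canola price defaults to $461.81/t (the 2010 crop price) and the discount
rate to 2%. A field = a cell; canola area per cell per year comes from the
4-year rotation maps, repeating if simulated longer. Canola revenue for
scenarios = (baseline + uplift) yield × area × price.

## Biodiversity intactness

Index (%) = clamp(intercept + Σ coefficient × footprint area, 0, 100),
with intercept 100 (no footprint = reference condition) and non-positive
per-class coefficients (defaults: road −0.90, trail −0.25, cutblock −0.45,
cropland −0.80, industrial −1.00, urban −1.10 % per ha). All are config;
`fit_footprint_model` refits them by OLS from training cells and reports
r². Variable-retention cutblocks contribute footprint in proportion to the
harvested fraction; this treats partial harvest as a smaller clearcut,
which is known to be pessimistic for retention systems — the limitation is
documented, not fixed. There is no recovery with cutblock age.

## Scenario engines

* **Harvest-strategy comparison**: paired replicates (same per-replicate
  seed for both modes, so the AAC draws match and the contrast isolates
  intensity), timber + carbon, then a water year and the biodiversity index
  on the post-harvest landscape, indicators standardized to the pre-harvest
  baseline. Pollination is excluded: crop production does not co-occur with
  commercial forestry.
* **ES-suite standardization**: each indicator is expressed as a percentage
  of its maximum across the compared landscapes, each indicator scaling
  only against itself (cross-ES comparisons of absolute values are
  inappropriate); the biodiversity index passes through unscaled.
* **Agricultural-expansion sweep**: for each conversion level (0–100% in 5%
  steps), every pasture-holding cell converts its entire pasture to
  cropland iff an independent uniform draw falls below the level — each
  level applied to the *baseline* landscape, not cumulatively. Newly
  converted cropland grows canola in one random year of the 4-year
  rotation. Within a replicate the same per-cell draws are reused across
  levels (common random numbers): every level still obeys the per-cell
  draw rule exactly, and the level series becomes nested, which removes
  sampling jitter from the production curves. Stochastic indicators are
  reported as replicate means with standard errors. Timber/carbon are
  excluded (no overlap with this land-use change).

## Synthetic landscape generator

The generator is first-class, tested code: it emulates a west-to-east
regional gradient (mountain forest → foothills forestry country → boreal
transition → parkland cropland → grassland), with per-region mixtures of
cell *variants* (e.g. parkland = 55% cropland cells, 30% pasture-dominated
cells, 15% peri-urban cells) jittered by a Dirichlet draw, so that
cropland, pasture and forest cells are distinct cells — the structure on
which conversion scenarios operate. The DEM falls west to east with a
central valley (so drainage converges on one mainstem) plus small noise;
precipitation falls 700 → 420 mm west to east. Stand ages are uniform on
0–120 years (a growing forest; regrowth outpaces default harvest removals
over 20 years). Mills (default 2) sit at the east edge of row-band FMUs
over the forested foothills/boreal zone, with AAC = 1.5 m³ per forest
hectare per year. River gauges are placed at the basin outlet and at the
most-accumulating river cell at or just downstream of each region group's
band. Everything is reproducible bitwise from one seed.

What the generator does **not** emulate: real drainage topology and lakes,
spatially autocorrelated landcover beyond the regional gradient, roads as
connected networks (road class is assigned per cell from its footprint),
vectorized field boundaries, inter-annual climate variability, and natural
disturbance. Passing tests therefore demonstrate internal correctness and
qualitative trade-off directions, not calibrated regional magnitudes.

## Numerical choices and degenerate inputs

* Composition closure tolerance 1e-6 relative; violations raise.
* Sink-fill epsilon 1e-6 m; D8 on unconditioned DEMs with interior flats
  raises rather than guessing.
* Water-year mass balance is exact to floating point (verified at 1e-9
  relative in tests).
* An empty river network (threshold above all accumulation) warns and
  routes everything to edge outlets; a monitoring point off the network
  raises.
* Zero-target or zero-AAC harvests produce empty ledgers, not errors;
  exhausted eligibility is recorded per FMU-year rather than raised.
* OLS refit raises on rank-deficient designs naming the collinear classes;
  a constant response yields zero coefficients and NaN r² with a warning.
* Seeds: one master seed; per-module substreams derive via SHA-256 of
  `"{seed}:{module}"` (stable as modules are added, always < 2³¹).

## Problem sizes

Default analysis sizes are chosen for interactive desk use: 20×20 cells for
exploration, 30×30 for the reported acceptance quantities (10 harvest
replicates, 4 sweep replicates), 40×40 and 50×50 in the heavier test-suite
checks. All complete in seconds to tens of seconds on one CPU; grids of
~10⁴ cells remain practical.

## Known limitations

* Absolute magnitudes depend on placeholder coefficient tables until
  calibrated; directions and orderings are the robust outputs.
* No wildfire or natural disturbance; no wood-product carbon release; no
  dead-organic-matter pool.
* No sub-annual hydrology, groundwater, in-stream processing or in-lake
  chemistry.
* The biodiversity index is community-averaged and linear: it cannot
  support single-species decisions and understates the benefit of variable
  retention.
* Landowner decisions are independent cells; no interdependencies, prices
  or soil-suitability targeting in the conversion scenario.
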