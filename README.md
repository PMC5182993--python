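# landes

Integrated, agent-based modelling of ecosystem services on a cellular
landscape: forest timber production and carbon storage, water purification
(nutrients and sediment), the pollination value of canola, and a
biodiversity-intactness index, with scenario engines for comparing timber
harvest strategies and for sweeping levels of agricultural expansion.

`landes` is written for land-use planners, resource economists and
ecologists who need to see how a *single* management decision — a change in
harvest practice, or converting pasture to cropland — moves a whole suite of
environmental and socioeconomic indicators at once, on a regional grid, at
desk scale. It trades fine process detail for integration, speed and
transparency: relative rankings and trade-off directions are the intended
products, not precise absolute predictions.

## The model

The landscape is a uniform grid of square cells (default 800 m, the 64-ha
"quarter section" at which many prairie land-use decisions are made). Each
cell stores the **areas** of every landcover and human-footprint class
present in it — sub-cell arrangement is deliberately discarded — plus
elevation, annual precipitation, a region label, forest stand cohorts and
soil factors. All sub-models run on an annual time step.

**Timber & carbon.** Stand volume V(age) and carbon density C(age) are
clamped polynomial curves per stand type (deciduous, pine, spruce,
mixedwood) × ecozone. Mill agents hold tenure over Forest Management Units
(FMUs); each year a mill realizes a truncated-normal fraction of its FMU's
Annual Allowable Cut and harvests eligible stands (age ≥ 80) in ascending
order of least-cost transport distance (Dijkstra over the road network)
until the volume target is met. Clearcutting removes a cell's eligible
volume; variable retention removes 25/50/75% chosen at random. Harvested
cohorts restart at age 0 and the cut area becomes "cutblock" footprint.
Cash flows discount to an NPV: `NPV = Σ_t CF_t / (1+r)^t`.

**Water purification.** One model year per call: runoff per cell is
precipitation × area-weighted runoff coefficients; N, P and TSS load into
runoff via area-weighted export coefficients (kg ha⁻¹ mm⁻¹, with distinct
regional coefficient sets); sediment comes from RUSLE, `A = R·K·LS·C·P`.
Each cell's runoff is a raindrop parcel descending the D8 flow field of the
sink-filled DEM; every transit cell retains a landcover-dependent share of
each load before the parcel reaches the river network, where flow and loads
accumulate downstream to monitoring gauges. Export coefficients can be
calibrated per region group against observed annual loads using Latin
Hypercube candidate sets.

**Pollination.** Wild-bee abundance is a saturating function of the natural
plus tame-pasture area within foraging distance (default 750 m) of each
canola field; the per-hectare yield uplift saturates in bee abundance.
Canola follows a 4-year rotation; uplift × price discounts to an NPV.

**Biodiversity.** A 0–100% intactness index per cell, linear (with
clamping) in the per-cell areas of each footprint class — roads, trails,
cutblocks, cropland, industrial, urban — refittable by OLS.

A built-in synthetic-landscape generator (west-to-east gradient from
mountain forest through foothills forestry country to parkland/grassland
agriculture, a drainable DEM, mills, FMUs, river gauges and crop rotations)
makes every module runnable and testable without external GIS data. Real
inputs enter through classified-raster summarization, ESRI ASCII grids and
CSV/YAML parameter tables.

## Worked example

```python
from landes import SyntheticConfig, generate_synthetic_landscape
from landes.forest_carbon import default_curve_library
from landes.timber_harvest import run_timber_simulation
from landes.water_purification import default_water_params, run_water_year
from landes.pollination import PollinationParams, run_pollination
from landes.biodiversity import BiodiversityModel, regional_mean_index

synth = generate_synthetic_landscape(SyntheticConfig(), seed=42)
land = synth.landscape

sim = run_timber_simulation(land, synth.mills, synth.fmus,
                            default_curve_library(), years=20,
                            mode="clearcut", seed=1)
water = run_water_year(land, default_water_params(),
                       synth.config.river_threshold, synth.monitoring_points)
poll = run_pollination(land, synth.rotation_maps, PollinationParams())
bio = regional_mean_index(land, BiodiversityModel())
```

On the default 20×20 synthetic landscape this prints:

```
timber NPV (clearcut, 20 yr): $24,633,205
carbon storage: 1,871,767 -> 1,924,907 t CO2e (+2.8%)
P retained on the landscape: 459 kg; supplied to streams: 8,551 kg
pollination NPV (4-yr rotation): $233,423 over 125 fields ($1,867/field)
biodiversity intactness: 86.3%
```

Read: twenty years of profit-maximizing clearcut harvest earns ~$24.6M in
present value while the forest estate still gains 2.8% carbon (regrowth
outpaces removals on this young landscape); the water year partitions every
kilogram of phosphorus between overland retention and stream delivery; wild
pollinators add ~$233k of discounted canola revenue across 125 fields; and
the human footprint has reduced average community intactness to 86% of the
reference condition.

The same operations are exposed on the command line
(`landes generate|timber|water|pollination|biodiversity|scenario|calibrate
--config cfg.yaml --seed N --out dir/`), which writes ASCII-grid maps, CSV
tables and a JSON manifest recording the config hash and seed of each run.

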