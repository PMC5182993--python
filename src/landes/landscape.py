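"""Cellular landscape data model and synthetic-landscape generator.

The landscape is a uniform grid of square cells (default 800 m, i.e. a
64-ha "quarter section").  Each cell stores the *areas* of the landcover
and human-footprint classes present in it — the sub-cell spatial
arrangement is deliberately discarded — plus elevation, annual
precipitation, an administrative region label, forest stand cohorts, and
soil-erosion factors.  Every other sub-model operates on this container.

Forest area is carried in two composition classes: ``forest`` (uncut) and
``cutblock`` (regenerating forest created by harvest, counted as human
footprint by the biodiversity model).  Stand cohorts partition the sum of
the two, so the growth model keeps operating on regenerating stands while
the footprint accounting sees the harvested area.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

# ---------------------------------------------------------------------------
# Class taxonomy
# ---------------------------------------------------------------------------

#: Natural (undeveloped) classes. ``pasture`` is semi-natural: seeded
#: perennial forage that still provides pollinator nesting habitat.
DEFAULT_NATURAL = ("forest", "grassland", "shrub", "water", "pasture")

#: Human-footprint classes. ``cutblock`` is regenerating harvested forest.
DEFAULT_FOOTPRINT = ("cropland", "road", "trail", "cutblock", "industrial", "urban")

REGIONS = ("Mountains", "Foothills", "Boreal", "Parkland", "Grassland")

#: Parameter-set (calibration) groups: the three plains regions are
#: topographically similar and share one coefficient set.
REGION_GROUP = {
    "Mountains": "mountains",
    "Foothills": "foothills",
    "Boreal": "plains",
    "Parkland": "plains",
    "Grassland": "plains",
}

ROAD_CLASSES = ("paved", "unpaved", "low", "none")

STAND_TYPES = ("deciduous", "pine", "spruce", "mixedwood")
ECOZONES = ("Montane Cordillera", "Boreal Plains")


@dataclass(frozen=True)
class Taxonomy:
    """User-overridable landcover/footprint class list."""

    natural: tuple[str, ...] = DEFAULT_NATURAL
    footprint: tuple[str, ...] = DEFAULT_FOOTPRINT

    @property
    def classes(self) -> tuple[str, ...]:
        return self.natural + self.footprint

    def check(self, name: str) -> None:
        if name not in self.natural and name not in self.footprint:
            raise ValueError(f"unknown landcover class {name!r}")


DEFAULT_TAXONOMY = Taxonomy()


# ---------------------------------------------------------------------------
# Cell-level types
# ---------------------------------------------------------------------------


@dataclass
class ForestStandCohort:
    """A (stand type × ecozone, age) unit of forest area within one cell."""

    stand_type: str
    ecozone: str
    age: int
    area: float  # ha

    def __post_init__(self) -> None:
        if self.stand_type not in STAND_TYPES:
            raise ValueError(f"unknown stand type {self.stand_type!r}")
        if self.ecozone not in ECOZONES:
            raise ValueError(f"unknown ecozone {self.ecozone!r}")
        if self.age < 0:
            raise ValueError("cohort age must be >= 0")
        if self.area < 0:
            raise ValueError("cohort area must be >= 0")


@dataclass
class Cell:
    row: int
    col: int
    elevation: float = 0.0  # m
    precipitation: float = 450.0  # mm / yr
    region: str = "Parkland"
    fmu_id: int | None = None
    road_class: str = "none"
    comp: dict[str, float] = field(default_factory=dict)  # class -> ha
    cohorts: list[ForestStandCohort] = field(default_factory=list)
    rusle_k: float = 0.3
    rusle_ls: float = 0.5
    canola_year: int | None = None  # rotation year (0..3) this cell grows canola

    def area_of(self, cls: str) -> float:
        return self.comp.get(cls, 0.0)

    @property
    def forest_basis(self) -> float:
        """Area (ha) carrying forest cohorts: uncut forest plus cutblocks."""
        return self.comp.get("forest", 0.0) + self.comp.get("cutblock", 0.0)


def validate_composition(
    cell: Cell,
    cell_area: float,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    rtol: float = 1e-6,
) -> None:
    """Check composition closure and non-negativity for one cell."""
    total = 0.0
    for cls, area in cell.comp.items():
        taxonomy.check(cls)
        if area < -rtol * cell_area:
            raise ValueError(f"negative area {area} for class {cls!r} in cell "
                             f"({cell.row}, {cell.col})")
        total += area
    if abs(total - cell_area) > rtol * cell_area:
        raise ValueError(
            f"composition of cell ({cell.row}, {cell.col}) sums to {total:.6f} ha, "
            f"expected {cell_area:.6f} ha")
    cohort_area = sum(c.area for c in cell.cohorts)
    if abs(cohort_area - cell.forest_basis) > max(rtol * cell_area, 1e-6):
        raise ValueError(
            f"cohort areas in cell ({cell.row}, {cell.col}) sum to {cohort_area:.6f} "
            f"ha but forest+cutblock area is {cell.forest_basis:.6f} ha")


# ---------------------------------------------------------------------------
# Grid landscape
# ---------------------------------------------------------------------------


@dataclass
class GridLandscape:
    """Uniform grid of cells with fractional landcover composition."""

    n_rows: int
    n_cols: int
    cell_size: float = 800.0  # m
    cells: list[list[Cell]] = field(default_factory=list)
    taxonomy: Taxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        if not self.cells:
            self.cells = [
                [Cell(row=r, col=c) for c in range(self.n_cols)]
                for r in range(self.n_rows)
            ]

    @property
    def cell_area(self) -> float:
        """Cell area in hectares (800 m -> 64 ha)."""
        return (self.cell_size / 100.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell(self, row: int, col: int) -> Cell:
        return self.cells[row][col]

    def iter_cells(self) -> Iterator[Cell]:
        for row in self.cells:
            yield from row

    def centroid(self, row: int, col: int) -> tuple[float, float]:
        """Planar centroid (x east, y north) in metres, origin at NW corner."""
        x = (col + 0.5) * self.cell_size
        y = (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def elevations(self) -> np.ndarray:
        return np.array([[c.elevation for c in row] for row in self.cells])

    def precipitation(self) -> np.ndarray:
        return np.array([[c.precipitation for c in row] for row in self.cells])

    def class_map(self, cls: str) -> np.ndarray:
        return np.array([[c.area_of(cls) for c in row] for row in self.cells])

    def total_area(self, cls: str) -> float:
        return float(sum(c.area_of(cls) for c in self.iter_cells()))

    def validate(self, rtol: float = 1e-6) -> None:
        for cell in self.iter_cells():
            validate_composition(cell, self.cell_area, self.taxonomy, rtol)

    def copy(self) -> "GridLandscape":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Summarizing a fine classified raster to the grid
# ---------------------------------------------------------------------------


def summarize_to_grid(
    raster: np.ndarray,
    pixel_size: float,
    code_map: Mapping[int, str],
    cell_size: float = 800.0,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    nodata: int | None = None,
    region: str = "Parkland",
    forest_cohort_age: int = 100,
    forest_stand_type: str = "mixedwood",
) -> GridLandscape:
    """Aggregate a per-pixel classified raster into per-cell class areas.

    The raster resolution must evenly divide the cell size and the raster
    dimensions must be an exact multiple of the aggregation factor.  Class
    areas within each cell sum to the cell area by construction; the
    sub-cell spatial arrangement is discarded by design.  Forest pixels
    produce a single placeholder cohort per cell (age/stand type supplied
    by the caller) since the raster carries no stand attributes.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("classified raster must be 2-D")
    factor = cell_size / pixel_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"pixel size {pixel_size} does not evenly divide cell size {cell_size}")
    factor = int(round(factor))
    if raster.shape[0] % factor or raster.shape[1] % factor:
        raise ValueError(
            f"raster shape {raster.shape} is not a multiple of the aggregation "
            f"factor {factor} (raster/grid misalignment)")
    for code in np.unique(raster):
        if nodata is not None and code == nodata:
            continue
        if int(code) not in code_map:
            raise ValueError(f"unknown class code {int(code)} in raster")
        taxonomy.check(code_map[int(code)])

    n_rows = raster.shape[0] // factor
    n_cols = raster.shape[1] // factor
    pixel_area = (pixel_size / 100.0) ** 2  # ha
    ecozone = ("Montane Cordillera"
               if region in ("Mountains", "Foothills") else "Boreal Plains")
    land = GridLandscape(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
                         taxonomy=taxonomy)
    for r in range(n_rows):
        for c in range(n_cols):
            block = raster[r * factor:(r + 1) * factor, c * factor:(c + 1) * factor]
            if nodata is not None and np.any(block == nodata):
                raise ValueError(
                    f"nodata pixels in block for cell ({r}, {c}); fill or mask "
                    "the input raster first")
            codes, counts = np.unique(block, return_counts=True)
            cell = land.cell(r, c)
            cell.region = region
            cell.comp = {code_map[int(k)]: float(n) * pixel_area
                         for k, n in zip(codes, counts)}
            forest = cell.comp.get("forest", 0.0)
            if forest > 0:
                cell.cohorts = [ForestStandCohort(forest_stand_type, ecozone,
                                                  forest_cohort_age, forest)]
    return land


def aggregate_to_cells(raster: np.ndarray, factor: int, how: str = "mean") -> np.ndarray:
    """Block-aggregate a fine raster (e.g. DEM, precipitation) to cell scale."""
    raster = np.asarray(raster, dtype=float)
    if raster.shape[0] % factor or raster.shape[1] % factor:
        raise ValueError("raster shape is not a multiple of the aggregation factor")
    n_rows, n_cols = raster.shape[0] // factor, raster.shape[1] // factor
    blocks = raster.reshape(n_rows, factor, n_cols, factor)
    if how == "mean":
        return blocks.mean(axis=(1, 3))
    if how == "min":
        return blocks.min(axis=(1, 3))
    raise ValueError(f"unknown aggregation {how!r}")


# ---------------------------------------------------------------------------
# Pasture -> cropland conversion (agricultural expansion primitive)
# ---------------------------------------------------------------------------


def convert_pasture_cell(
    cell: Cell,
    draw: float,
    proportion: float,
    rotation_draw: int = 0,
) -> bool:
    """Convert the cell's entire pasture to cropland if ``draw < proportion``.

    ``rotation_draw`` (0..3) assigns newly converted cropland to grow canola
    in exactly one year of the 4-year rotation, used only when the cell had
    no prior canola year.  Returns True if conversion happened.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"conversion proportion must be in [0, 1], got {proportion}")
    if not 0 <= rotation_draw <= 3:
        raise ValueError("rotation_draw must be in 0..3")
    pasture = cell.comp.get("pasture", 0.0)
    if draw < proportion and pasture > 0:
        cell.comp["pasture"] = 0.0
        cell.comp["cropland"] = cell.comp.get("cropland", 0.0) + pasture
        if cell.canola_year is None:
            cell.canola_year = int(rotation_draw)
        return True
    return False


# ---------------------------------------------------------------------------
# Synthetic landscape generator
# ---------------------------------------------------------------------------

#: Per-region landcover archetypes laid out on a west-to-east gradient:
#: mountains/forest in the west grading into parkland/cropland and grassland
#: in the east.  Each region is a mixture of weighted cell variants
#: (name, weight, class fractions), so cropland cells, pasture-dominated
#: cells and forest cells are distinct cells rather than one blended
#: composition — conversion scenarios then create new crop fields out of
#: pasture cells, as happens on real parkland landscapes.
DEFAULT_ARCHETYPES: dict[str, list[tuple[str, float, dict[str, float]]]] = {
    "Mountains": [
        ("alpine_forest", 1.0, {"forest": 0.70, "grassland": 0.10, "shrub": 0.12,
                                "water": 0.05, "trail": 0.03}),
    ],
    "Foothills": [
        ("forestry", 0.92, {"forest": 0.78, "grassland": 0.05, "shrub": 0.06,
                            "road": 0.02, "cutblock": 0.05, "trail": 0.04}),
        ("pasture", 0.08, {"pasture": 0.60, "forest": 0.10, "grassland": 0.05,
                           "shrub": 0.05, "road": 0.05, "water": 0.15}),
    ],
    "Boreal": [
        ("forest", 0.50, {"forest": 0.70, "shrub": 0.10, "grassland": 0.05,
                          "water": 0.05, "road": 0.03, "industrial": 0.07}),
        ("crop", 0.30, {"cropland": 0.55, "pasture": 0.10, "forest": 0.15,
                        "grassland": 0.10, "road": 0.05, "industrial": 0.05}),
        ("pasture", 0.20, {"pasture": 0.60, "forest": 0.10, "grassland": 0.10,
                           "road": 0.05, "water": 0.15}),
    ],
    "Parkland": [
        ("crop", 0.55, {"cropland": 0.65, "pasture": 0.07, "forest": 0.08,
                        "grassland": 0.10, "road": 0.05, "urban": 0.03,
                        "water": 0.02}),
        ("pasture", 0.30, {"pasture": 0.75, "grassland": 0.05, "forest": 0.05,
                           "road": 0.05, "water": 0.10}),
        ("urban", 0.15, {"urban": 0.30, "cropland": 0.30, "road": 0.10,
                         "grassland": 0.15, "pasture": 0.10, "water": 0.05}),
    ],
    "Grassland": [
        ("grass", 0.45, {"grassland": 0.70, "pasture": 0.10, "shrub": 0.08,
                         "road": 0.04, "water": 0.08}),
        ("crop", 0.35, {"cropland": 0.60, "grassland": 0.15, "pasture": 0.10,
                        "road": 0.05, "shrub": 0.05, "water": 0.05}),
        ("pasture", 0.20, {"pasture": 0.70, "grassland": 0.10, "shrub": 0.05,
                           "road": 0.05, "water": 0.10}),
    ],
}

#: Stand-type mixture by ecozone for synthetic cohorts.
STAND_WEIGHTS = {
    "Montane Cordillera": {"pine": 0.40, "spruce": 0.40, "mixedwood": 0.15,
                           "deciduous": 0.05},
    "Boreal Plains": {"deciduous": 0.40, "mixedwood": 0.25, "spruce": 0.25,
                      "pine": 0.10},
}


@dataclass
class SyntheticConfig:
    """Study conditions for the built-in synthetic landscape.

    Defaults emulate the modelled watershed: a west-east gradient from
    mountain forest through foothills forestry country to parkland/grassland
    agriculture, a DEM falling west to east with a central valley so drainage
    converges on one mainstem, higher precipitation in the west, two
    mills with FMU tenure in the forested bands, and cropland on a 4-year
    canola rotation.
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_size: float = 800.0
    region_fractions: tuple = (("Mountains", 0.15), ("Foothills", 0.20),
                               ("Boreal", 0.20), ("Parkland", 0.25),
                               ("Grassland", 0.20))
    archetypes: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_ARCHETYPES))
    dirichlet_concentration: float = 60.0
    age_low: int = 0
    age_high: int = 120
    n_cohorts: int = 2
    base_elevation: float = 500.0   # m at the east edge
    relief: float = 600.0           # west-east drop, m
    valley_depth: float = 150.0     # pull toward the central row, m
    dem_noise: float = 8.0          # m, sd
    precip_west: float = 700.0      # mm/yr
    precip_east: float = 420.0
    precip_noise: float = 10.0
    n_mills: int = 2
    aac_per_forest_ha: float = 1.5  # m3/ha/yr of FMU forest area
    fraction_mean: float = 0.85     # realized share of the AAC
    fraction_sd: float = 0.08
    river_threshold: int = 10       # cells of upstream accumulation
    canola_fraction: float = 1.0    # share of a cell's cropland in canola, in its year


@dataclass
class SyntheticLandscape:
    """Generator output bundle: landscape plus agents and auxiliary maps."""

    landscape: GridLandscape
    mills: list
    fmus: list
    monitoring_points: list[tuple[str, int, int]]
    rotation_maps: "RotationMaps"
    config: SyntheticConfig
    seed: int


@dataclass
class RotationMaps:
    """Four annual per-cell canola-area maps (ha), one per rotation year."""

    years: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if sorted(self.years) != [0, 1, 2, 3]:
            raise ValueError("rotation maps must cover exactly years 0..3")

    def canola_area(self, year: int) -> np.ndarray:
        """Canola map for simulation year ``year`` (1-based), repeating every 4."""
        return self.years[(year - 1) % 4]


def build_rotation_maps(land: GridLandscape, canola_fraction: float = 1.0) -> RotationMaps:
    years = {y: np.zeros(land.shape) for y in range(4)}
    for cell in land.iter_cells():
        if cell.canola_year is not None:
            crop = cell.area_of("cropland")
            if crop > 0:
                years[cell.canola_year][cell.row, cell.col] = crop * canola_fraction
    return RotationMaps(years)


def _region_bands(config: SyntheticConfig) -> list[str]:
    """Region label per column, west to east."""
    labels: list[str] = []
    total = sum(f for _, f in config.region_fractions)
    edges = []
    acc = 0.0
    for name, frac in config.region_fractions:
        acc += frac / total
        edges.append((name, acc))
    for c in range(config.n_cols):
        pos = (c + 0.5) / config.n_cols
        for name, edge in edges:
            if pos <= edge:
                labels.append(name)
                break
        else:
            labels.append(config.region_fractions[-1][0])
    return labels


def generate_synthetic_landscape(config: SyntheticConfig, seed: int) -> SyntheticLandscape:
    """Generate a reproducible synthetic landscape plus mills, FMUs,
    monitoring points and crop-rotation maps.

    The DEM is a west-east ramp with a central valley and small noise, so
    after sink filling it drains to the east edge; landcover composition per
    cell is a Dirichlet jitter of the column band's regional archetype.
    """
    if config.n_rows < 8 or config.n_cols < 8:
        raise ValueError("synthetic landscape must be at least 8x8")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    land = GridLandscape(n_rows=config.n_rows, n_cols=config.n_cols,
                         cell_size=config.cell_size)
    cell_area = land.cell_area
    bands = _region_bands(config)
    nr, nc = config.n_rows, config.n_cols

    for r in range(nr):
        for c in range(nc):
            cell = land.cell(r, c)
            region = bands[c]
            cell.region = region
            ecozone = ("Montane Cordillera"
                       if region in ("Mountains", "Foothills") else "Boreal Plains")
            variants = config.archetypes[region]
            weights = np.array([w for _, w, _ in variants], dtype=float)
            arch = variants[rng.choice(len(variants), p=weights / weights.sum())][2]
            classes = [k for k, v in arch.items() if v > 0]
            alphas = np.array([arch[k] for k in classes]) * config.dirichlet_concentration
            fr = rng.dirichlet(alphas)
            areas = fr * cell_area
            areas *= cell_area / areas.sum()
            cell.comp = dict(zip(classes, areas.tolist()))

            # elevation: ramp west->east, valley toward the centre row, noise
            west = 1.0 - c / (nc - 1)
            valley = abs(r - (nr - 1) / 2.0) / nr
            cell.elevation = (config.base_elevation + config.relief * west
                              + config.valley_depth * valley
                              + rng.normal(0.0, config.dem_noise))
            cell.precipitation = max(0.0, (config.precip_east
                                           + (config.precip_west - config.precip_east) * west
                                           + rng.normal(0.0, config.precip_noise)))

            # road class from the footprint present
            road = cell.comp.get("road", 0.0)
            if road >= 0.035 * cell_area:
                cell.road_class = "paved"
            elif road > 0:
                cell.road_class = "unpaved"
            elif cell.comp.get("trail", 0.0) > 0:
                cell.road_class = "low"
            else:
                cell.road_class = "none"

            cell.rusle_k = float(rng.uniform(0.20, 0.40))
            slope = config.relief / ((nc - 1) * config.cell_size) + valley * 0.02
            cell.rusle_ls = float(np.clip(0.3 + 25.0 * slope + rng.uniform(0, 0.2),
                                          0.1, 3.0))

            # forest cohorts (cutblock area regenerates from age 0)
            basis = cell.forest_basis
            if basis > 0:
                weights = STAND_WEIGHTS[ecozone]
                names = list(weights)
                probs = np.array([weights[n] for n in names])
                probs = probs / probs.sum()
                shares = rng.dirichlet(np.ones(config.n_cohorts) * 2.0)
                cohorts = []
                cut = cell.comp.get("cutblock", 0.0)
                uncut = basis - cut
                for share in shares:
                    stand = str(rng.choice(names, p=probs))
                    age = int(rng.integers(config.age_low, config.age_high + 1))
                    cohorts.append(ForestStandCohort(stand, ecozone, age,
                                                     share * uncut))
                if cut > 0:
                    stand = str(rng.choice(names, p=probs))
                    age = int(rng.integers(0, 21))  # recent harvest
                    cohorts.append(ForestStandCohort(stand, ecozone, age, cut))
                cell.cohorts = [k for k in cohorts if k.area > 0]

            # canola rotation year for cropland cells
            if cell.comp.get("cropland", 0.0) > 0:
                cell.canola_year = int(rng.integers(0, 4))

    mills, fmus = _place_mills_and_fmus(land, config, rng)
    monitors = _place_monitoring_points(land, config)
    rotation = build_rotation_maps(land, config.canola_fraction)
    return SyntheticLandscape(land, mills, fmus, monitors, rotation, config, seed)


def _place_mills_and_fmus(land: GridLandscape, config: SyntheticConfig, rng):
    from .timber_harvest import FMU, Mill, DEFAULT_MILL_ECONOMICS

    zone = [cell for cell in land.iter_cells()
            if cell.region in ("Foothills", "Boreal") and cell.area_of("forest") > 0]
    if config.n_mills == 0:
        return [], []
    if config.n_mills > len(zone):
        raise ValueError(
            f"infeasible config: {config.n_mills} mills but only {len(zone)} "
            "forested cells in the tenure zone")
    rows = sorted({cell.row for cell in zone})
    band_size = max(1, math.ceil(len(rows) / config.n_mills))
    mills, fmus = [], []
    mill_types = ("pulp", "lumber", "OSB")
    for i in range(config.n_mills):
        band_rows = set(rows[i * band_size:(i + 1) * band_size])
        members = [cell for cell in zone if cell.row in band_rows]
        if not members:
            continue
        for cell in members:
            cell.fmu_id = i
        forest_ha = sum(cell.area_of("forest") for cell in members)
        fmus.append(FMU(id=i, cells={(c.row, c.col) for c in members},
                        aac=config.aac_per_forest_ha * forest_ha,
                        fraction_mean=config.fraction_mean,
                        fraction_sd=config.fraction_sd))
        # mill sits at the eastern edge of its FMU band (near the road net)
        site = max(members, key=lambda cell: (cell.col, -cell.row))
        econ = DEFAULT_MILL_ECONOMICS[mill_types[i % 3]]
        mills.append(Mill(id=i, row=site.row, col=site.col,
                          mill_type=mill_types[i % 3],
                          price=econ["price"], conversion=econ["conversion"],
                          unit_cost=econ["unit_cost"], fmu_ids=frozenset({i})))
    return mills, fmus


def _place_monitoring_points(land: GridLandscape, config: SyntheticConfig):
    from .water_purification import (fill_sinks, d8_flow_directions,
                                     extract_river_network)

    filled = fill_sinks(land.elevations())
    flow = d8_flow_directions(filled)
    network = extract_river_network(flow, config.river_threshold)
    if not network.river_cells:
        return []
    acc = flow.accumulation
    monitors: list[tuple[str, int, int]] = []
    used: set[tuple[int, int]] = set()
    outlet = max(network.river_cells, key=lambda rc: acc[rc])
    monitors.append(("outlet", outlet[0], outlet[1]))
    used.add(outlet)
    bands = _region_bands(config)
    group_end: dict[str, int] = {}
    for c, name in enumerate(bands):
        group_end[REGION_GROUP[name]] = c
    for group in ("mountains", "foothills", "plains"):
        if group not in group_end:
            continue
        # the nearest river cell at or just downstream of the group's band
        limit = min(group_end[group] + 1, config.n_cols - 1)
        best = None
        while best is None and limit < config.n_cols:
            candidates = [rc for rc in network.river_cells
                          if rc[1] <= limit and rc not in used]
            if candidates:
                best = max(candidates, key=lambda rc: acc[rc])
            else:
                limit += 1
        if best is not None:
            monitors.append((group, best[0], best[1]))
            used.add(best)
    return monitors
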