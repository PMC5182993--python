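"""Pollination service: extra canola yield from wild bees nesting nearby.

Ground-nesting wild bees, the dominant pollinators in the region, nest in
natural (forest, grassland, shrub) and semi-natural (tame pasture) land and
forage within a limited radius (default 750 m, resolved at cell scale by
centroid distance).  Bee abundance is a saturating function of the nesting
habitat area within that radius; the per-hectare canola yield uplift is in
turn a saturating function of bee abundance, so the uplift is zero without
habitat and monotone non-decreasing in habitat.  The default functional
forms are Michaelis-Menten; both are pluggable, since fitted field
relationships belong in config.

Canola placement follows a 4-year rotation (each cropland cell grows canola
in exactly one rotation year); multi-year value is discounted to an NPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .landscape import GridLandscape, RotationMaps

DEFAULT_HABITAT_CLASSES = ("forest", "grassland", "shrub", "pasture")


@dataclass
class PollinationParams:
    radius_m: float = 750.0  # pollinator foraging distance
    abundance_max: float = 1.0  # asymptotic bee-abundance index
    habitat_half_sat_ha: float = 150.0  # habitat giving half-max abundance
    uplift_max_t_ha: float = 0.46  # asymptotic extra yield, t/ha
    uplift_half_sat: float = 0.30  # abundance giving half-max uplift
    baseline_yield_t_ha: float = 1.54  # yield with no wild pollinators
    price_per_t: float = 461.81  # canola price, $/t (2010 crop price)
    discount_rate: float = 0.02
    habitat_classes: tuple[str, ...] = DEFAULT_HABITAT_CLASSES
    abundance_fn: Callable[[float, "PollinationParams"], float] | None = None
    uplift_fn: Callable[[float, "PollinationParams"], float] | None = None

    def __post_init__(self) -> None:
        for name in ("radius_m", "abundance_max", "habitat_half_sat_ha",
                     "uplift_max_t_ha", "uplift_half_sat", "baseline_yield_t_ha",
                     "price_per_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@lru_cache(maxsize=32)
def _neighbor_offsets(radius_m: float, cell_size: float) -> tuple[tuple[int, int], ...]:
    """Offsets (dr, dc) whose centroid distance is within the radius,
    including (0, 0)."""
    reach = int(radius_m // cell_size) + 1
    out = []
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            if (dr * dr + dc * dc) * cell_size ** 2 <= radius_m ** 2:
                out.append((dr, dc))
    return tuple(out)


def nesting_habitat_area(
    land: GridLandscape,
    row: int,
    col: int,
    radius_m: float | None = None,
    habitat_classes: Sequence[str] = DEFAULT_HABITAT_CLASSES,
    params: PollinationParams | None = None,
) -> float:
    """Natural + semi-natural area (ha) within foraging distance of the focal
    cell (centroid distance, focal cell included)."""
    if params is not None:
        radius_m = params.radius_m
        habitat_classes = params.habitat_classes
    if radius_m is None:
        radius_m = 750.0
    if radius_m < 0:
        raise ValueError("radius must be >= 0")
    total = 0.0
    for dr, dc in _neighbor_offsets(radius_m, land.cell_size):
        r, c = row + dr, col + dc
        if 0 <= r < land.n_rows and 0 <= c < land.n_cols:
            comp = land.cell(r, c).comp
            total += sum(comp.get(cls, 0.0) for cls in habitat_classes)
    return total


def bee_abundance(habitat_ha: float, params: PollinationParams) -> float:
    """Bee-abundance index: saturating in nesting habitat, zero at zero."""
    if habitat_ha < 0:
        raise ValueError("habitat area must be >= 0")
    if params.abundance_fn is not None:
        return params.abundance_fn(habitat_ha, params)
    return params.abundance_max * habitat_ha / (habitat_ha + params.habitat_half_sat_ha)


def uplift_per_ha(abundance: float, params: PollinationParams) -> float:
    """Extra canola yield (t/ha) attributable to the given bee abundance."""
    if params.uplift_fn is not None:
        return params.uplift_fn(abundance, params)
    if abundance <= 0:
        return 0.0
    return params.uplift_max_t_ha * abundance / (abundance + params.uplift_half_sat)


def pollination_uplift(
    land: GridLandscape,
    row: int,
    col: int,
    canola_ha: float,
    params: PollinationParams,
) -> tuple[float, float]:
    """Extra yield (t) and its value ($) for one field-year.  A cell growing
    no canola that year contributes zero by contract."""
    if canola_ha <= 0:
        return 0.0, 0.0
    habitat = nesting_habitat_area(land, row, col, params=params)
    uplift_t = canola_ha * uplift_per_ha(bee_abundance(habitat, params), params)
    return uplift_t, uplift_t * params.price_per_t


@dataclass
class PollinationResult:
    npv_map: np.ndarray  # $ pollination NPV per cell
    total_value: float  # $ landscape pollination NPV
    per_field_mean: float  # $ mean NPV over canola-growing cells
    n_fields: int
    revenue_npv: float  # $ total canola revenue NPV (baseline + uplift)


def run_pollination(
    land: GridLandscape,
    rotation: RotationMaps,
    params: PollinationParams,
    years: int = 4,
) -> PollinationResult:
    """Value wild pollination over ``years`` (rotation repeating every 4),
    discounted at the configured rate from t = 1."""
    npv_map = np.zeros(land.shape)
    revenue = 0.0
    fields: set[tuple[int, int]] = set()
    # bee abundance depends only on the (static) landscape, not the rotation
    uplift_cache: dict[tuple[int, int], float] = {}
    for year in range(1, years + 1):
        canola = rotation.canola_area(year)
        disc = (1.0 + params.discount_rate) ** year
        for row, col in zip(*np.nonzero(canola)):
            rc = (int(row), int(col))
            area = float(canola[rc])
            fields.add(rc)
            if rc not in uplift_cache:
                habitat = nesting_habitat_area(land, *rc, params=params)
                uplift_cache[rc] = uplift_per_ha(bee_abundance(habitat, params), params)
            uplift_t = area * uplift_cache[rc]
            npv_map[rc] += uplift_t * params.price_per_t / disc
            revenue += ((params.baseline_yield_t_ha * area + uplift_t)
                        * params.price_per_t / disc)
    total = float(npv_map.sum())
    n_fields = len(fields)
    per_field = total / n_fields if n_fields else 0.0
    return PollinationResult(npv_map=npv_map, total_value=total,
                             per_field_mean=per_field, n_fields=n_fields,
                             revenue_npv=revenue)
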