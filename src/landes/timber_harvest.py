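"""Mill agents scheduling annual timber harvest under the Annual Allowable Cut.

Each mill holds tenure over one or more Forest Management Units (FMUs).  In
every simulated year a mill realizes a fraction of its FMU's AAC (truncated
normal, reflecting that the full AAC is rarely cut), then harvests eligible
stands (age >= 80 by default) in ascending order of transport cost to the
mill until the volume target is met, overshooting by at most the final cell
because a selected cell is cut whole.  Clearcutting removes all eligible
volume in a cell; variable retention removes 25/50/75% chosen at random,
altering intensity but never spatial pattern.  Harvested cohorts regenerate
from age 0 and the harvested area moves to the ``cutblock`` footprint class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .forest_carbon import CurveLibrary, age_forests, total_carbon
from .landscape import Cell, ForestStandCohort, GridLandscape

#: Traversal cost ($/m³ per 800-m cell step) by road class: high-speed paved
#: roads are cheap to haul on, unpaved moderate, low-speed corridors
#: (pipelines, cut-lines) slow, roadless cells slowest.
DEFAULT_TRAVERSAL_COSTS = {"paved": 0.4, "unpaved": 1.2, "low": 2.5, "none": 5.0}

DEFAULT_MILL_ECONOMICS = {
    "pulp": {"price": 180.0, "conversion": 0.90, "unit_cost": 50.0},
    "lumber": {"price": 150.0, "conversion": 1.00, "unit_cost": 50.0},
    "OSB": {"price": 140.0, "conversion": 1.10, "unit_cost": 50.0},
}

RETENTION_FRACTIONS = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class Mill:
    id: int
    row: int
    col: int
    mill_type: str  # pulp | lumber | OSB
    price: float  # $ per unit product
    conversion: float  # product units per m³ raw timber
    unit_cost: float  # harvest + processing $ per m³
    fmu_ids: frozenset[int]

    def __post_init__(self) -> None:
        if self.price < 0 or self.conversion < 0 or self.unit_cost < 0:
            raise ValueError("mill prices, costs and conversion must be >= 0")


@dataclass
class FMU:
    id: int
    cells: set[tuple[int, int]]
    aac: float  # m³/yr
    fraction_mean: float = 0.85
    fraction_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.aac < 0:
            raise ValueError("AAC must be >= 0")


@dataclass
class HarvestRecord:
    year: int
    mill_id: int
    fmu_id: int
    row: int
    col: int
    volume: float  # m³ removed
    fraction: float
    transport_cost: float  # $/m³
    net_cashflow: float  # $


@dataclass
class FmuYearSummary:
    """Per FMU-year scheduling diagnostics, for the greedy-harvest contract."""

    year: int
    mill_id: int
    fmu_id: int
    target: float
    harvested_volume: float
    n_cells: int
    max_harvested_cost: float
    min_unharvested_cost: float  # inf if eligibles exhausted
    last_cell_volume: float
    exhausted: bool


class HarvestLedger:
    """Accumulates per-cell harvest records and per-FMU-year summaries."""

    def __init__(self) -> None:
        self.records: list[HarvestRecord] = []
        self.summaries: list[FmuYearSummary] = []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.summaries])

    def cashflow(self, mill_id: int, year: int) -> float:
        return sum(r.net_cashflow for r in self.records
                   if r.mill_id == mill_id and r.year == year)


# ---------------------------------------------------------------------------
# Transport cost surface
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


def build_cost_surface(
    land: GridLandscape,
    mill: Mill,
    traversal_costs: dict[str, float] | None = None,
) -> np.ndarray:
    """Least accumulated transport cost ($/m³) from every cell to the mill.

    Single-source shortest path on the 8-connected grid; the cost of a step
    is the traversal cost of the *destination* cell's road class, times √2
    for diagonal moves.  Cost at the mill cell is 0.
    """
    costs = dict(DEFAULT_TRAVERSAL_COSTS if traversal_costs is None else traversal_costs)
    for cls, value in costs.items():
        if value <= 0:
            raise ValueError(f"traversal cost for road class {cls!r} must be > 0")
    nr, nc = land.shape
    if not (0 <= mill.row < nr and 0 <= mill.col < nc):
        raise ValueError(f"mill {mill.id} at ({mill.row}, {mill.col}) is off the grid")
    step_cost = np.array(
        [[costs[land.cell(r, c).road_class] for c in range(nc)] for r in range(nr)])

    rows, cols, weights = [], [], []
    for r in range(nr):
        for c in range(nc):
            u = r * nc + c
            for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1),
                           (0, -1), (-1, -1), (-1, 0), (-1, 1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    rows.append(u)
                    cols.append(r2 * nc + c2)
                    diag = _SQRT2 if dr and dc else 1.0
                    weights.append(step_cost[r2, c2] * diag)
    graph = coo_matrix((weights, (rows, cols)), shape=(nr * nc, nr * nc))
    dist = dijkstra(graph.tocsr(), directed=True, indices=mill.row * nc + mill.col)
    # graph is symmetric in structure; distances mill->cell equal cell->mill
    # because the step cost depends only on the cell being entered and haul
    # routes are traversed in both directions.
    return dist.reshape(nr, nc)


# ---------------------------------------------------------------------------
# Harvest scheduling
# ---------------------------------------------------------------------------


def draw_aac_fraction(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Realized fraction of the AAC: normal(mean, sd) truncated to [0, 1]."""
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"AAC fraction mean must be in [0, 1], got {mean}")
    if sd < 0:
        raise ValueError("AAC fraction sd must be >= 0")
    if sd == 0:
        return mean
    from scipy.stats import truncnorm
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def eligible_stands(
    fmu: FMU, land: GridLandscape, min_age: int = 80
) -> list[tuple[Cell, ForestStandCohort]]:
    """Cohorts in FMU cells with age >= min_age and positive area."""
    out = []
    for (r, c) in sorted(fmu.cells):
        cell = land.cell(r, c)
        for cohort in cell.cohorts:
            if cohort.age >= min_age and cohort.area > 0:
                out.append((cell, cohort))
    return out


def apply_harvest(cell: Cell, cohort: ForestStandCohort, fraction: float) -> Cell:
    """Harvest ``fraction`` of a cohort: that share regenerates at age 0 and
    its area moves from the ``forest`` to the ``cutblock`` footprint class.
    Total cohort area is conserved."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"harvest fraction must be in (0, 1], got {fraction}")
    harvested = fraction * cohort.area
    if fraction == 1.0:
        cohort.age = 0
    else:
        cohort.area -= harvested
        cell.cohorts.append(ForestStandCohort(cohort.stand_type, cohort.ecozone,
                                              0, harvested))
    moved = min(harvested, cell.comp.get("forest", 0.0))
    if moved > 0:
        cell.comp["forest"] = cell.comp["forest"] - moved
        cell.comp["cutblock"] = cell.comp.get("cutblock", 0.0) + moved
    return cell


def schedule_annual_harvest(
    mill: Mill,
    fmu: FMU,
    land: GridLandscape,
    curves: CurveLibrary,
    mode: str,
    rng: np.random.Generator,
    cost_surface: np.ndarray,
    target: float,
    year: int = 0,
    min_age: int = 80,
    excluded: set[tuple[int, int]] | None = None,
) -> tuple[list[HarvestRecord], FmuYearSummary]:
    """Greedy harvest of eligible cells in ascending transport-cost order
    until cumulative volume reaches ``target`` (one-cell overshoot allowed)
    or eligibles are exhausted.  Ties broken by ascending (row, col).

    ``excluded`` cells (already harvested earlier in a simulation) are
    skipped: volume retained by variable-retention harvest stays retained,
    and cut cells are closed to re-entry during the planning horizon.
    """
    if mode not in ("clearcut", "variable_retention"):
        raise ValueError(f"unknown harvest mode {mode!r}")
    if cost_surface is None:
        raise ValueError("cost surface required before scheduling harvest")
    excluded = excluded or set()
    eligibles = eligible_stands(fmu, land, min_age)
    by_cell: dict[tuple[int, int], list[ForestStandCohort]] = {}
    for cell, cohort in eligibles:
        if (cell.row, cell.col) not in excluded:
            by_cell.setdefault((cell.row, cell.col), []).append(cohort)
    ordered = sorted(by_cell, key=lambda rc: (cost_surface[rc], rc[0], rc[1]))

    records: list[HarvestRecord] = []
    cum = 0.0
    last_volume = 0.0
    i = 0
    for i, rc in enumerate(ordered):
        if cum >= target:
            break
        cell = land.cell(*rc)
        fraction = 1.0 if mode == "clearcut" else float(rng.choice(RETENTION_FRACTIONS))
        volume = 0.0
        for cohort in by_cell[rc]:
            volume += curves.growth(cohort.stand_type, cohort.ecozone).value(cohort.age) \
                * cohort.area * fraction
            apply_harvest(cell, cohort, fraction)
        transport = float(cost_surface[rc])
        margin = mill.conversion * mill.price - mill.unit_cost - transport
        records.append(HarvestRecord(year, mill.id, fmu.id, rc[0], rc[1],
                                     volume, fraction, transport, volume * margin))
        cum += volume
        last_volume = volume
    else:
        i = len(ordered)
    harvested_rcs = {(r.row, r.col) for r in records}
    remaining = [rc for rc in ordered if rc not in harvested_rcs]
    summary = FmuYearSummary(
        year=year, mill_id=mill.id, fmu_id=fmu.id, target=target,
        harvested_volume=cum, n_cells=len(records),
        max_harvested_cost=max((r.transport_cost for r in records), default=0.0),
        min_unharvested_cost=(min(cost_surface[rc] for rc in remaining)
                              if remaining else math.inf),
        last_cell_volume=last_volume,
        exhausted=not remaining and cum < target,
    )
    return records, summary


def mill_cashflow(records: Iterable[HarvestRecord], mill: Mill) -> float:
    """Annual cash flow: Σ volume × (conversion × price − unit cost − transport)."""
    return sum(r.volume * (mill.conversion * mill.price - mill.unit_cost
                           - r.transport_cost)
               for r in records if r.mill_id == mill.id)


def npv(cashflows: Sequence[float], discount_rate: float) -> float:
    """Net present value with cash flows at t = 1..T."""
    if discount_rate <= -1:
        raise ValueError("discount rate must be > -1")
    return sum(cf / (1.0 + discount_rate) ** t
               for t, cf in enumerate(cashflows, start=1))


# ---------------------------------------------------------------------------
# Multi-year simulation
# ---------------------------------------------------------------------------


@dataclass
class TimberSimResult:
    npv_total: float
    npv_per_mill: dict[int, float]
    carbon_series: list[float]  # index 0 = pre-simulation baseline
    ledger: HarvestLedger
    harvested_cells: set[tuple[int, int]]
    npv_map: np.ndarray  # per-cell discounted net harvest value ($)
    landscape: GridLandscape  # post-harvest state


def run_timber_simulation(
    land: GridLandscape,
    mills: Sequence[Mill],
    fmus: Sequence[FMU],
    curves: CurveLibrary,
    years: int = 20,
    mode: str = "clearcut",
    seed: int = 0,
    discount_rate: float = 0.02,
    traversal_costs: dict[str, float] | None = None,
    min_age: int = 80,
) -> TimberSimResult:
    """Annual loop: age forests, then each mill schedules and applies harvest
    in its FMUs; cash flows are discounted to an NPV.  The input landscape is
    not mutated; cost surfaces are built once (static road network)."""
    land = land.copy()
    fmu_by_id = {f.id: f for f in fmus}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    surfaces = {m.id: build_cost_surface(land, m, traversal_costs) for m in mills}
    ledger = HarvestLedger()
    cashflows: dict[int, list[float]] = {m.id: [] for m in mills}
    carbon = [total_carbon(land, curves)]
    npv_map = np.zeros(land.shape)
    harvested_so_far: set[tuple[int, int]] = set()

    for year in range(1, years + 1):
        age_forests(land)
        for mill in sorted(mills, key=lambda m: m.id):
            year_cash = 0.0
            for fid in sorted(mill.fmu_ids):
                fmu = fmu_by_id[fid]
                fraction = draw_aac_fraction(fmu.fraction_mean, fmu.fraction_sd, rng)
                target = fraction * fmu.aac
                records, summary = schedule_annual_harvest(
                    mill, fmu, land, curves, mode, rng, surfaces[mill.id],
                    target, year=year, min_age=min_age,
                    excluded=harvested_so_far)
                harvested_so_far.update((r.row, r.col) for r in records)
                ledger.records.extend(records)
                ledger.summaries.append(summary)
                disc = (1.0 + discount_rate) ** year
                for rec in records:
                    year_cash += rec.net_cashflow
                    npv_map[rec.row, rec.col] += rec.net_cashflow / disc
            cashflows[mill.id].append(year_cash)
        carbon.append(total_carbon(land, curves))

    npv_per_mill = {mid: npv(cfs, discount_rate) for mid, cfs in cashflows.items()}
    harvested = {(r.row, r.col) for r in ledger.records}
    return TimberSimResult(
        npv_total=sum(npv_per_mill.values()),
        npv_per_mill=npv_per_mill,
        carbon_series=carbon,
        ledger=ledger,
        harvested_cells=harvested,
        npv_map=npv_map,
        landscape=land,
    )
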