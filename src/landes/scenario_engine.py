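"""Scenario analyses coupling the sub-models.

Three demonstration engines:

* ``compare_harvest_strategies`` — paired clearcut vs. variable-retention
  timber simulations, with the water and biodiversity models run on the
  post-harvest landscape and indicators standardized to the pre-harvest
  baseline (pollination excluded: crop production does not overlap
  commercial forestry).
* ``standardize_es_suite`` — expresses each landscape's value of each
  ecosystem service as a percentage of the maximum across the compared
  landscapes (the biodiversity index, already a percentage, passes through).
* ``agricultural_expansion_sweep`` — converts the region's remaining pasture
  to cropland in 5% increments, each level applied independently to the
  baseline landscape, and records canola revenue, pollination value (total
  and per-field), phosphorus supply and the mean biodiversity index
  (timber/carbon excluded: harvest does not overlap this land-use change).

Stochastic indicators are reported as means over replicate seeds.  Within a
replicate the sweep reuses one uniform draw per pasture cell across all
conversion levels (a cell converts wherever the draw falls below the
level), which satisfies the per-cell conversion rule at every level while
making the level series nested — a common-random-numbers design that
removes sampling jitter from the production curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import biodiversity as biodiv
from .forest_carbon import CurveLibrary, total_carbon
from .landscape import (GridLandscape, SyntheticLandscape, build_rotation_maps,
                        convert_pasture_cell)
from .pollination import PollinationParams, run_pollination
from .timber_harvest import run_timber_simulation
from .water_purification import WaterParams, run_water_year


@dataclass
class ScenarioResult:
    label: str
    indicators: dict[str, float]
    deltas: dict[str, float] = field(default_factory=dict)  # vs. baseline
    seeds: tuple[int, ...] = ()


def _water_indicators(land: GridLandscape, water_params: WaterParams,
                      river_threshold: int, monitors) -> dict[str, float]:
    result = run_water_year(land, water_params, river_threshold, monitors)
    out = {}
    for s in ("N", "P", "TSS"):
        out[f"{s}_supplied_kg"] = float(result.supplied[s].sum())
    return out


def compare_harvest_strategies(
    synth: SyntheticLandscape,
    curves: CurveLibrary,
    water_params: WaterParams,
    biodiv_model: biodiv.BiodiversityModel,
    years: int = 20,
    n_replicates: int = 20,
    seed: int = 0,
    discount_rate: float = 0.02,
) -> tuple[ScenarioResult, ScenarioResult, pd.DataFrame]:
    """Paired comparison of clearcutting vs. variable retention.

    Each replicate runs both modes from the same per-replicate seed, so the
    AAC-fraction draws match and the comparison isolates harvest intensity.
    Indicator deltas are expressed relative to the pre-harvest baseline
    (timber NPV relative to the clearcut mean, which has no baseline).
    Returns (clearcut result, variable-retention result, per-replicate table).
    """
    land0 = synth.landscape
    monitors = synth.monitoring_points
    threshold = synth.config.river_threshold
    baseline = {"carbon_t": total_carbon(land0, curves),
                "biodiversity_pct": biodiv.regional_mean_index(land0, biodiv_model),
                **_water_indicators(land0, water_params, threshold, monitors)}

    rows = []
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)]
    for rep_seed in seeds:
        for mode in ("clearcut", "variable_retention"):
            sim = run_timber_simulation(land0, synth.mills, synth.fmus, curves,
                                        years=years, mode=mode, seed=rep_seed,
                                        discount_rate=discount_rate)
            post = sim.landscape
            row = {"mode": mode, "seed": rep_seed,
                   "timber_npv": sim.npv_total,
                   "cells_harvested": len(sim.harvested_cells),
                   "carbon_t": sim.carbon_series[-1],
                   "carbon_change_t": sim.carbon_series[-1] - sim.carbon_series[0],
                   "biodiversity_pct": biodiv.regional_mean_index(post, biodiv_model),
                   **_water_indicators(post, water_params, threshold, monitors)}
            rows.append(row)
    table = pd.DataFrame(rows)

    results = []
    for mode in ("clearcut", "variable_retention"):
        sub = table[table["mode"] == mode]
        indicators = {k: float(sub[k].mean()) for k in sub.columns
                      if k not in ("mode", "seed")}
        deltas = {k: indicators[k] - baseline[k] for k in baseline}
        results.append(ScenarioResult(label=mode, indicators=indicators,
                                      deltas=deltas, seeds=tuple(seeds)))
    return results[0], results[1], table


def standardize_es_suite(values: pd.DataFrame,
                         passthrough: Sequence[str] = ("biodiversity_pct",)
                         ) -> pd.DataFrame:
    """Express each indicator as a percentage of its maximum across the
    compared landscapes (rows).  Columns in ``passthrough`` (already
    percentages, e.g. the biodiversity index) are returned unscaled."""
    if len(values) < 2:
        raise ValueError("need at least two landscapes to standardize across")
    if (values.drop(columns=[c for c in passthrough if c in values], errors="ignore")
            .lt(0).any().any()):
        raise ValueError("indicator values must be >= 0")
    out = values.copy().astype(float)
    for col in values.columns:
        if col in passthrough:
            continue
        top = values[col].max()
        if top == 0:
            warnings.warn(f"indicator {col!r} is zero for every landscape; "
                          "scores set to 0", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = 100.0 * values[col] / top
    return out


def _apply_conversion(land: GridLandscape, draws: np.ndarray,
                      rotation_draws: np.ndarray, proportion: float) -> int:
    converted = 0
    for cell in land.iter_cells():
        if cell.comp.get("pasture", 0.0) > 0:
            if convert_pasture_cell(cell, float(draws[cell.row, cell.col]),
                                    proportion,
                                    int(rotation_draws[cell.row, cell.col])):
                converted += 1
    return converted


def agricultural_expansion_sweep(
    synth: SyntheticLandscape,
    poll_params: PollinationParams,
    water_params: WaterParams,
    biodiv_model: biodiv.BiodiversityModel,
    proportions: Sequence[float] | None = None,
    n_replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Pasture-to-cropland conversion sweep (default 0..100% in 5% steps).

    Every level is an independent conversion of the baseline landscape (not
    cumulative).  Returns a long-format table (level, replicate, indicator,
    value); aggregate with ``sweep_summary``.
    """
    if proportions is None:
        proportions = np.round(np.arange(0.0, 1.0001, 0.05), 4)
    land0 = synth.landscape
    monitors = synth.monitoring_points
    threshold = synth.config.river_threshold
    rows = []
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)]
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        draws = rng.uniform(size=land0.shape)
        rotation_draws = rng.integers(0, 4, size=land0.shape)
        for level in proportions:
            land = land0.copy()
            n_converted = _apply_conversion(land, draws, rotation_draws,
                                            float(level))
            rotation = build_rotation_maps(land, synth.config.canola_fraction)
            poll = run_pollination(land, rotation, poll_params)
            water = run_water_year(land, water_params, threshold, monitors)
            bio = biodiv.regional_mean_index(land, biodiv_model)
            indicators = {
                "cells_converted": float(n_converted),
                "pasture_area_ha": land.total_area("pasture"),
                "cropland_area_ha": land.total_area("cropland"),
                "canola_revenue": poll.revenue_npv,
                "pollination_total": poll.total_value,
                "pollination_per_field": poll.per_field_mean,
                "P_supplied_kg": float(water.supplied["P"].sum()),
                "biodiversity_pct": bio,
            }
            for name, value in indicators.items():
                rows.append({"level": float(level), "replicate": rep,
                             "indicator": name, "value": value})
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged sweep: one row per level, one column per indicator,
    with standard errors in ``<indicator>_se`` columns."""
    mean = sweep.pivot_table(index="level", columns="indicator", values="value",
                             aggfunc="mean")
    se = sweep.pivot_table(index="level", columns="indicator", values="value",
                           aggfunc=lambda v: np.std(v, ddof=1) / np.sqrt(len(v))
                           if len(v) > 1 else 0.0)
    se.columns = [f"{c}_se" for c in se.columns]
    return pd.concat([mean, se], axis=1).reset_index()
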