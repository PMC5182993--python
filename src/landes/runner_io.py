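"""Configuration, raster/CSV I/O, seed management, and the command line.

All randomness in a run derives from one master seed: each module draws a
named substream seed from it, so adding a module never perturbs the streams
of existing ones.  Rasters are written as ESRI ASCII grids (a plain-text
format readable by any GIS); every run writes a JSON manifest recording the
config hash, seed and package version so outputs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biodiversity as biodiv
from .forest_carbon import CurveLibrary, default_curve_library
from .landscape import (GridLandscape, SyntheticConfig, SyntheticLandscape,
                        generate_synthetic_landscape)
from .pollination import PollinationParams, run_pollination
from .scenario_engine import (agricultural_expansion_sweep,
                              compare_harvest_strategies, sweep_summary)
from .timber_harvest import run_timber_simulation
from .water_purification import (WaterParams, calibrate_export_coefficients,
                                 default_water_params, latin_hypercube_sample,
                                 run_water_year)

# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------


def module_seed(master_seed: int, name: str) -> int:
    """Deterministic per-module substream seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# ESRI ASCII grid raster I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(values: np.ndarray, path: str | Path, cell_size: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999.0) -> Path:
    """Write a per-cell map as an ESRI ASCII grid.  NaNs become nodata."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("grid values must be 2-D")
    path = Path(path)
    out = np.where(np.isnan(values), nodata, values)
    header = (f"ncols {values.shape[1]}\nnrows {values.shape[0]}\n"
              f"xllcorner {xllcorner:.6f}\nyllcorner {yllcorner:.6f}\n"
              f"cellsize {cell_size:.6f}\nNODATA_value {nodata:.6f}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        meta[key.lower()] = float(value)
    values = np.loadtxt(lines[6:])
    values = np.atleast_2d(values)
    if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"grid body shape {values.shape} does not match header "
                         f"({int(meta['nrows'])}, {int(meta['ncols'])})")
    nodata = meta.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, meta


def write_composition_csv(land: GridLandscape, path: str | Path) -> Path:
    rows = [{"row": cell.row, "col": cell.col, "class": cls, "area_ha": area}
            for cell in land.iter_cells() for cls, area in sorted(cell.comp.items())
            if area > 0]
    path = Path(path)
    pd.DataFrame(rows, columns=["row", "col", "class", "area_ha"]).to_csv(
        path, index=False)
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _require(cfg: dict, *path: str):
    node = cfg
    walked = []
    for key in path:
        walked.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config table {'.'.join(walked)!r}")
        node = node[key]
    return node


def synthetic_from_config(cfg: dict, seed: int) -> SyntheticLandscape:
    spec = dict(_require(cfg, "landscape", "synthetic"))
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(spec) - known
    if unknown:
        raise ConfigError(f"unknown synthetic landscape fields {sorted(unknown)}")
    return generate_synthetic_landscape(SyntheticConfig(**spec),
                                        module_seed(seed, "landscape"))


def water_params_from_config(cfg: dict) -> WaterParams:
    params = default_water_params()
    section = cfg.get("water", {})
    for name in ("runoff", "rusle_c"):
        if name in section:
            getattr(params, name).update(section[name])
    if "retention" in section:
        for cls, subs in section["retention"].items():
            params.retention.setdefault(cls, {}).update(subs)
    if "export" in section:
        for group, classes in section["export"].items():
            for cls, subs in classes.items():
                params.export.setdefault(group, {}).setdefault(cls, {}).update(subs)
    return params


def curves_from_config(cfg: dict) -> CurveLibrary:
    section = cfg.get("forest", {})
    if "curves" in section:
        return CurveLibrary.from_records(section["curves"])
    return default_curve_library()


def pollination_params_from_config(cfg: dict) -> PollinationParams:
    spec = dict(cfg.get("pollination", {}))
    spec.pop("years", None)
    if "habitat_classes" in spec:
        spec["habitat_classes"] = tuple(spec["habitat_classes"])
    return PollinationParams(**spec)


def biodiversity_model_from_config(cfg: dict) -> biodiv.BiodiversityModel:
    spec = cfg.get("biodiversity", {})
    model = biodiv.BiodiversityModel()
    if "intercept" in spec:
        model.intercept = float(spec["intercept"])
    if "coefficients" in spec:
        model.coefficients.update(spec["coefficients"])
    return model


def write_manifest(out_dir: Path, config_path: str | Path | None, seed: int,
                   outputs: list[str]) -> Path:
    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {"version": __version__, "seed": seed,
                "config_sha256": config_hash, "outputs": sorted(outputs)}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def main() -> None:
    """Integrated ecosystem-services landscape model."""


def _common(fn):
    fn = click.option("--config", "config_path", required=True,
                      type=click.Path(exists=True))(fn)
    fn = click.option("--seed", default=0, show_default=True, type=int)(fn)
    fn = click.option("--out", "out_dir", required=True, type=click.Path())(fn)
    return fn


def _setup(config_path: str, seed: int, out_dir: str):
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = synthetic_from_config(cfg, seed)
    return cfg, out, synth


@main.command()
@_common
def generate(config_path: str, seed: int, out_dir: str) -> None:
    """Generate the synthetic landscape and write its layers to disk."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    land = synth.landscape
    outputs = [
        str(write_ascii_grid(land.elevations(), out / "dem.asc", land.cell_size)),
        str(write_ascii_grid(land.precipitation(), out / "precipitation.asc",
                             land.cell_size)),
        str(write_composition_csv(land, out / "composition.csv")),
    ]
    rotation_rows = []
    for year, arr in synth.rotation_maps.years.items():
        for r, c in zip(*np.nonzero(arr)):
            rotation_rows.append({"row": int(r), "col": int(c), "year": year,
                                  "canola_ha": float(arr[r, c])})
    rot_path = out / "rotation.csv"
    pd.DataFrame(rotation_rows,
                 columns=["row", "col", "year", "canola_ha"]).to_csv(rot_path,
                                                                     index=False)
    outputs.append(str(rot_path))
    agents = {
        "mills": [{"id": m.id, "row": m.row, "col": m.col, "type": m.mill_type}
                  for m in synth.mills],
        "fmus": [{"id": f.id, "aac_m3": f.aac, "n_cells": len(f.cells)}
                 for f in synth.fmus],
        "monitoring_points": [{"label": label, "row": r, "col": c}
                              for label, r, c in synth.monitoring_points],
    }
    agents_path = out / "agents.yaml"
    agents_path.write_text(yaml.safe_dump(agents))
    outputs.append(str(agents_path))
    write_manifest(out, config_path, seed, outputs)
    click.echo(f"generated {land.n_rows}x{land.n_cols} landscape in {out}")


@main.command()
@_common
@click.option("--mode", default="clearcut", show_default=True,
              type=click.Choice(["clearcut", "variable_retention"]))
@click.option("--years", default=20, show_default=True, type=int)
def timber(config_path: str, seed: int, out_dir: str, mode: str, years: int) -> None:
    """Run the timber harvest and forest carbon simulation."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    curves = curves_from_config(cfg)
    sim = run_timber_simulation(synth.landscape, synth.mills, synth.fmus, curves,
                                years=years, mode=mode,
                                seed=module_seed(seed, "timber"))
    outputs = []
    ledger_path = out / "harvest_ledger.csv"
    sim.ledger.to_frame().to_csv(ledger_path, index=False)
    outputs.append(str(ledger_path))
    carbon_path = out / "carbon_trajectory.csv"
    pd.DataFrame({"year": range(len(sim.carbon_series)),
                  "carbon_t_co2e": sim.carbon_series}).to_csv(carbon_path,
                                                              index=False)
    outputs.append(str(carbon_path))
    outputs.append(str(write_ascii_grid(sim.npv_map, out / "timber_npv.asc",
                                        synth.landscape.cell_size)))
    write_manifest(out, config_path, seed, outputs)
    click.echo(f"timber NPV ({mode}, {years} yr): ${sim.npv_total:,.0f}")


@main.command()
@_common
def water(config_path: str, seed: int, out_dir: str) -> None:
    """Run one water-purification model year."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    params = water_params_from_config(cfg)
    result = run_water_year(synth.landscape, params,
                            synth.config.river_threshold,
                            synth.monitoring_points)
    outputs = []
    for s in ("N", "P", "TSS", "sediment"):
        for kind, maps in (("loading", result.loading),
                           ("removal", result.removal),
                           ("supplied", result.supplied)):
            path = out / f"{s}_{kind}.asc"
            write_ascii_grid(maps[s], path, synth.landscape.cell_size)
            outputs.append(str(path))
    mon_path = out / "monitoring.csv"
    result.monitoring.to_csv(mon_path, index=False)
    outputs.append(str(mon_path))
    write_manifest(out, config_path, seed, outputs)
    click.echo(result.monitoring.to_string(index=False))


@main.command()
@_common
def pollination(config_path: str, seed: int, out_dir: str) -> None:
    """Run the 4-year pollination valuation."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    params = pollination_params_from_config(cfg)
    result = run_pollination(synth.landscape, synth.rotation_maps, params,
                             years=int(cfg.get("pollination", {}).get("years", 4)))
    outputs = [str(write_ascii_grid(result.npv_map, out / "pollination_npv.asc",
                                    synth.landscape.cell_size))]
    totals = out / "pollination_totals.csv"
    pd.DataFrame([{"total_value": result.total_value,
                   "per_field_mean": result.per_field_mean,
                   "n_fields": result.n_fields,
                   "revenue_npv": result.revenue_npv}]).to_csv(totals, index=False)
    outputs.append(str(totals))
    write_manifest(out, config_path, seed, outputs)
    click.echo(f"pollination NPV: ${result.total_value:,.0f} over "
               f"{result.n_fields} fields")


@main.command()
@_common
def biodiversity(config_path: str, seed: int, out_dir: str) -> None:
    """Compute the biodiversity-intactness index map."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    model = biodiversity_model_from_config(cfg)
    values = biodiv.biodiversity_map(synth.landscape, model)
    outputs = [str(write_ascii_grid(values, out / "biodiversity.asc",
                                    synth.landscape.cell_size))]
    summary = out / "biodiversity_summary.csv"
    pd.DataFrame([{"mean_index_pct": float(values.mean()),
                   "min_index_pct": float(values.min()),
                   "max_index_pct": float(values.max())}]).to_csv(summary,
                                                                  index=False)
    outputs.append(str(summary))
    write_manifest(out, config_path, seed, outputs)
    click.echo(f"mean biodiversity index: {values.mean():.1f}%")


@main.command()
@_common
@click.option("--replicates", default=None, type=int,
              help="override scenario.n_replicates")
def scenario(config_path: str, seed: int, out_dir: str,
             replicates: int | None) -> None:
    """Run the scenario analysis named in the config (harvest_comparison or
    expansion_sweep)."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    section = _require(cfg, "scenario")
    kind = section.get("kind", "harvest_comparison")
    n_rep = replicates or int(section.get("n_replicates", 20))
    outputs = []
    if kind == "harvest_comparison":
        cc, vr, table = compare_harvest_strategies(
            synth, curves_from_config(cfg), water_params_from_config(cfg),
            biodiversity_model_from_config(cfg),
            years=int(section.get("years", 20)), n_replicates=n_rep,
            seed=module_seed(seed, "scenario"))
        path = out / "harvest_comparison.csv"
        table.to_csv(path, index=False)
        outputs.append(str(path))
        click.echo(f"mean NPV clearcut ${cc.indicators['timber_npv']:,.0f} vs "
                   f"variable retention ${vr.indicators['timber_npv']:,.0f}")
    elif kind == "expansion_sweep":
        sweep = agricultural_expansion_sweep(
            synth, pollination_params_from_config(cfg),
            water_params_from_config(cfg), biodiversity_model_from_config(cfg),
            n_replicates=n_rep, seed=module_seed(seed, "scenario"))
        long_path = out / "expansion_sweep.csv"
        sweep.to_csv(long_path, index=False)
        outputs.append(str(long_path))
        summary_path = out / "expansion_sweep_summary.csv"
        sweep_summary(sweep).to_csv(summary_path, index=False)
        outputs.append(str(summary_path))
        click.echo(f"sweep complete: {len(sweep)} rows")
    else:
        raise ConfigError(f"unknown scenario kind {kind!r}")
    write_manifest(out, config_path, seed, outputs)


@main.command()
@_common
@click.option("--observed", "observed_path", required=True,
              type=click.Path(exists=True),
              help="CSV of observed loads: point, substance, load_kg")
def calibrate(config_path: str, seed: int, out_dir: str,
              observed_path: str) -> None:
    """Latin-Hypercube calibration of the nutrient export coefficients."""
    cfg, out, synth = _setup(config_path, seed, out_dir)
    section = _require(cfg, "calibration")
    n_sets = int(section.get("n_sets", 10))
    scale_lo = float(section.get("scale_low", 0.5))
    scale_hi = float(section.get("scale_high", 2.0))
    base = water_params_from_config(cfg)
    samples = latin_hypercube_sample(
        {g: (scale_lo, scale_hi) for g in ("mountains", "foothills", "plains")},
        n_sets, module_seed(seed, "calibration"))
    candidates = []
    for sample in samples:
        export = {g: {cls: {s: v * sample[g] for s, v in subs.items()}
                      for cls, subs in classes.items()}
                  for g, classes in base.export.items()}
        candidates.append(base.with_export(export))
    observed = pd.read_csv(observed_path)
    groups = {label: (label if label in ("mountains", "foothills", "plains")
                      else "plains")
              for label, _, _ in synth.monitoring_points}
    result = calibrate_export_coefficients(
        synth.landscape, observed, candidates, synth.monitoring_points,
        groups, synth.config.river_threshold)
    path = out / "calibration.csv"
    result.objective.to_csv(path, index=False)
    write_manifest(out, config_path, seed, [str(path)])
    click.echo(f"selected candidate per group: {result.best_index}")


if __name__ == "__main__":
    main()
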