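import pytest

from landes.forest_carbon import AgeCurve, CurveLibrary, default_curve_library
from landes.landscape import (ECOZONES, STAND_TYPES, ForestStandCohort,
                              GridLandscape, SyntheticConfig,
                              generate_synthetic_landscape)
from landes.water_purification import default_water_params


@pytest.fixture(scope="session")
def synth20():
    """Default 20x20 synthetic landscape; treat as read-only (copy to mutate)."""
    return generate_synthetic_landscape(SyntheticConfig(), seed=42)


@pytest.fixture(scope="session")
def curves():
    return default_curve_library()


@pytest.fixture(scope="session")
def water_params():
    return default_water_params()


def make_landscape(n_rows, n_cols, comp, cell_size=800.0, precipitation=450.0,
                   region="Parkland", elevation_fn=None, cohorts_fn=None):
    """Uniform test landscape; ``comp`` maps class -> fraction of cell area."""
    land = GridLandscape(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)
    area = land.cell_area
    for cell in land.iter_cells():
        cell.comp = {cls: frac * area for cls, frac in comp.items()}
        cell.precipitation = precipitation
        cell.region = region
        if elevation_fn is not None:
            cell.elevation = elevation_fn(cell.row, cell.col)
        if cohorts_fn is not None:
            cell.cohorts = cohorts_fn(cell.row, cell.col)
        elif cell.comp.get("forest", 0.0) > 0:
            cell.cohorts = [ForestStandCohort("mixedwood", "Boreal Plains", 100,
                                              cell.comp["forest"])]
    return land


def uniform_curve_library(volume_coeffs=(0.0, 1.0), carbon_coeffs=(0.0, 2.0),
                          age_max=200.0):
    """Curve library with one shared linear curve per stratum (hand oracle)."""
    lib = {}
    for stand in STAND_TYPES:
        for zone in ECOZONES:
            lib[(stand, zone)] = (AgeCurve(stand, zone, volume_coeffs, age_max),
                                  AgeCurve(stand, zone, carbon_coeffs, age_max))
    return CurveLibrary(lib)
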