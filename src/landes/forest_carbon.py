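"""Stand-level timber volume and carbon storage as functions of age.

Merchantable volume V(age) (m³/ha) and combined above- plus below-ground
carbon density C(age) (t CO₂e/ha) are polynomial curves per stand type ×
ecozone stratum, clamped at zero and held flat beyond ``age_max`` so that
fitted polynomials cannot diverge outside their data range.  The default
library uses smoothstep cubics (sigmoidal rise to a plateau) with
stratum-specific asymptotes — a documented qualitative stand-in; real
deployments supply fitted coefficients via config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landscape import ECOZONES, STAND_TYPES, GridLandscape


@dataclass(frozen=True)
class AgeCurve:
    """Polynomial curve of age, clamped >= 0 and flat beyond ``age_max``."""

    stand_type: str
    ecozone: str
    coefficients: tuple[float, ...]  # ascending degree
    age_max: float = 200.0

    def value(self, age: float) -> float:
        if age < 0:
            raise ValueError(f"age must be >= 0, got {age}")
        a = min(age, self.age_max)
        return max(0.0, float(np.polynomial.polynomial.polyval(a, self.coefficients)))


GrowthCurve = AgeCurve
CarbonCurve = AgeCurve


def stand_volume(curve: GrowthCurve, age: float) -> float:
    """Merchantable volume density (m³/ha) of a stand at ``age`` years."""
    return curve.value(age)


def stand_carbon(curve: CarbonCurve, age: float) -> float:
    """Carbon density (t CO₂e/ha, above- + below-ground) at ``age`` years."""
    return curve.value(age)


class CurveLibrary:
    """Growth and carbon curves for all 8 stand type × ecozone strata."""

    def __init__(self, curves: dict[tuple[str, str], tuple[GrowthCurve, CarbonCurve]]):
        for stand in STAND_TYPES:
            for zone in ECOZONES:
                if (stand, zone) not in curves:
                    raise ValueError(
                        f"missing growth/carbon curve for stratum ({stand!r}, {zone!r})")
        self._curves = dict(curves)

    def growth(self, stand_type: str, ecozone: str) -> GrowthCurve:
        try:
            return self._curves[(stand_type, ecozone)][0]
        except KeyError:
            raise ValueError(f"no curve for stratum ({stand_type!r}, {ecozone!r})")

    def carbon(self, stand_type: str, ecozone: str) -> CarbonCurve:
        try:
            return self._curves[(stand_type, ecozone)][1]
        except KeyError:
            raise ValueError(f"no curve for stratum ({stand_type!r}, {ecozone!r})")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "CurveLibrary":
        """Build from config records with keys stand_type, ecozone, kind
        ('volume'|'carbon'), coefficients, age_max."""
        partial: dict[tuple[str, str], dict[str, AgeCurve]] = {}
        for rec in records:
            key = (rec["stand_type"], rec["ecozone"])
            curve = AgeCurve(rec["stand_type"], rec["ecozone"],
                             tuple(float(x) for x in rec["coefficients"]),
                             float(rec.get("age_max", 200.0)))
            partial.setdefault(key, {})[rec["kind"]] = curve
        curves = {}
        for key, kinds in partial.items():
            if "volume" not in kinds or "carbon" not in kinds:
                raise ValueError(f"stratum {key} needs both volume and carbon curves")
            curves[key] = (kinds["volume"], kinds["carbon"])
        return cls(curves)


def _smoothstep(v_max: float, age_max: float) -> tuple[float, float, float, float]:
    # cubic through (0,0) and (age_max, v_max) with zero slope at both ends
    return (0.0, 0.0, 3.0 * v_max / age_max ** 2, -2.0 * v_max / age_max ** 3)


#: Plateau volume (m³/ha) and carbon (t CO₂e/ha) by stand type; the
#: Montane Cordillera multiplier reflects slower montane growth.
_VMAX = {"deciduous": 250.0, "pine": 340.0, "spruce": 400.0, "mixedwood": 300.0}
_CMAX = {"deciduous": 550.0, "pine": 700.0, "spruce": 820.0, "mixedwood": 640.0}
_ZONE_FACTOR = {"Montane Cordillera": 0.85, "Boreal Plains": 1.0}
_CARBON_FLOOR = 40.0  # t/ha residual below-ground pool at age 0


def default_curve_library(age_max: float = 180.0) -> CurveLibrary:
    """Placeholder curve set with the qualitative shape of fitted stand
    curves: sigmoidal rise to a stratum-specific plateau."""
    curves = {}
    for stand in STAND_TYPES:
        for zone in ECOZONES:
            f = _ZONE_FACTOR[zone]
            growth = AgeCurve(stand, zone, _smoothstep(_VMAX[stand] * f, age_max),
                              age_max)
            c0, c1, c2, c3 = _smoothstep(_CMAX[stand] * f - _CARBON_FLOOR, age_max)
            carbon = AgeCurve(stand, zone, (_CARBON_FLOOR, c1, c2, c3), age_max)
            curves[(stand, zone)] = (growth, carbon)
    return CurveLibrary(curves)


def age_forests(land: GridLandscape) -> GridLandscape:
    """Advance every forest cohort by one year, in place."""
    for cell in land.iter_cells():
        for cohort in cell.cohorts:
            cohort.age += 1
    return land


def total_carbon(land: GridLandscape, curves: CurveLibrary) -> float:
    """Landscape forest carbon (t CO₂e): Σ C(age) × cohort area."""
    total = 0.0
    for cell in land.iter_cells():
        for cohort in cell.cohorts:
            total += curves.carbon(cohort.stand_type, cohort.ecozone).value(cohort.age) \
                * cohort.area
    return total


def total_volume(land: GridLandscape, curves: CurveLibrary) -> float:
    """Landscape standing merchantable volume (m³)."""
    total = 0.0
    for cell in land.iter_cells():
        for cohort in cell.cohorts:
            total += curves.growth(cohort.stand_type, cohort.ecozone).value(cohort.age) \
                * cohort.area
    return total
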