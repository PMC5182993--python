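"""Biodiversity-intactness index from human-footprint areas.

The index (0-100%) summarizes how far the ecological community of a cell
has shifted from its reference (footprint-free) state; 100% means no
change.  It is a linear function of the per-cell areas of each footprint
class, clamped to [0, 100] — a simplified surrogate for the full
multi-species intactness model, refittable by OLS on training cells.  The
default coefficients are configurable placeholders (all non-positive, so
the index is monotone non-increasing in every footprint area).  There is
no temporal element: cutblocks count as footprint regardless of age, which
is known to overstate the impact of variable-retention harvest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landscape import DEFAULT_FOOTPRINT, Cell, GridLandscape

DEFAULT_COEFFICIENTS = {
    "road": -0.90,
    "trail": -0.25,
    "cutblock": -0.45,
    "cropland": -0.80,
    "industrial": -1.00,
    "urban": -1.10,
}  # % per ha


@dataclass
class BiodiversityModel:
    intercept: float = 100.0  # % at zero footprint (reference condition)
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    lower: float = 0.0
    upper: float = 100.0
    r_squared: float | None = None


def footprint_vector(cell: Cell,
                     classes: Sequence[str] = DEFAULT_FOOTPRINT) -> dict[str, float]:
    """Per-class footprint areas (ha) of one cell."""
    return {cls: cell.comp.get(cls, 0.0) for cls in classes}


def biodiversity_index(footprint: Mapping[str, float],
                       model: BiodiversityModel) -> float:
    """Index (%) = clamp(intercept + Σ coeff × area, 0, 100)."""
    value = model.intercept
    for cls, area in footprint.items():
        if cls not in model.coefficients:
            raise ValueError(f"no biodiversity coefficient for footprint class {cls!r}")
        value += model.coefficients[cls] * area
    return float(np.clip(value, model.lower, model.upper))


def biodiversity_map(land: GridLandscape, model: BiodiversityModel) -> np.ndarray:
    classes = tuple(model.coefficients)
    out = np.zeros(land.shape)
    for cell in land.iter_cells():
        out[cell.row, cell.col] = biodiversity_index(
            footprint_vector(cell, classes), model)
    return out


def regional_mean_index(
    land: GridLandscape,
    model: BiodiversityModel,
    mask: np.ndarray | None = None,
) -> float:
    """Unweighted mean index over the masked cells (all cells by default)."""
    values = biodiversity_map(land, model)
    if mask is None:
        return float(values.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match the landscape grid")
    if not mask.any():
        raise ValueError("mask selects no cells")
    return float(values[mask].mean())


def fit_footprint_model(
    footprints: Sequence[Mapping[str, float]],
    observed: Sequence[float],
    clamp: tuple[float, float] = (0.0, 100.0),
) -> BiodiversityModel:
    """OLS refit of the footprint regression.

    Requires at least n_classes + 1 training cells.  Raises on a
    rank-deficient design, naming the collinear classes.  A constant
    response yields zero coefficients and an undefined r² (NaN, with a
    warning).
    """
    classes = sorted({cls for fp in footprints for cls in fp})
    y = np.asarray(observed, dtype=float)
    if len(footprints) != len(y):
        raise ValueError("footprints and observed index must have equal length")
    if len(y) < len(classes) + 1:
        raise ValueError(
            f"need at least {len(classes) + 1} training cells for "
            f"{len(classes)} footprint classes, got {len(y)}")
    X = np.column_stack([np.ones(len(y))]
                        + [[fp.get(cls, 0.0) for fp in footprints] for cls in classes])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [("intercept", *classes)[j] for j in np.argsort(diag)[: X.shape[1] - rank]]
        raise ValueError(f"rank-deficient design: collinear classes {sorted(bad)}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant observed index: r² is undefined", stacklevel=2)
        r2 = float("nan")
        beta = np.concatenate([[y[0]], np.zeros(len(classes))])
    else:
        r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
    return BiodiversityModel(intercept=float(beta[0]),
                             coefficients=dict(zip(classes, beta[1:].tolist())),
                             lower=clamp[0], upper=clamp[1], r_squared=r2)
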