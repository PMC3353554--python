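"""Phenological map products: full-flowering masks, class maps, gradients.

Grid cells with kriged phase between 1.5 and 2.5 (inclusive) are classified
as populations at full flowering — the window of maximum pollen shedding —
and the fraction of valid map area inside that band is the quantity compared
against the airborne pollen curve.  Class maps round each cell half-up to the
nearest integer phenophase for legend-style display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .data import PhenoGrid, SamplingPoint

__all__ = [
    "FloweringMask",
    "classify_full_flowering",
    "phase_class_map",
    "elevation_gradient_summary",
]

FULL_FLOWERING_LO = 1.5
FULL_FLOWERING_HI = 2.5


@dataclass
class FloweringMask:
    """Boolean full-flowering classification of a phenological grid."""

    xll: float
    yll: float
    cellsize: float
    mask: np.ndarray  # bool, True where lo <= value <= hi
    valid: np.ndarray  # bool, False at NODATA cells
    area_fraction: float  # true cells / valid cells


def classify_full_flowering(
    grid: PhenoGrid,
    lo: float = FULL_FLOWERING_LO,
    hi: float = FULL_FLOWERING_HI,
) -> FloweringMask:
    """Mask the cells whose phase lies in [lo, hi] (bounds inclusive)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    valid = grid.valid_mask()
    if not valid.any():
        raise ValueError("grid has no valid cells")
    mask = valid & (grid.values >= lo) & (grid.values <= hi)
    return FloweringMask(
        xll=grid.xll, yll=grid.yll, cellsize=grid.cellsize,
        mask=mask, valid=valid,
        area_fraction=float(mask.sum() / valid.sum()),
    )


def phase_class_map(grid: PhenoGrid) -> np.ndarray:
    """Integer phenophase class per cell, round-half-up, NODATA preserved as -1."""
    valid = grid.valid_mask()
    classes = np.full(grid.values.shape, -1, dtype=int)
    classes[valid] = np.clip(
        np.floor(grid.values[valid] + 0.5).astype(int), 0, 4
    )
    return classes


def elevation_gradient_summary(
    grid: PhenoGrid, points: list[SamplingPoint]
) -> tuple[float, bool]:
    """Spearman rank correlation between site altitude and mapped phase.

    Returns ``(rho, defined)``.  Negative rho means lower-altitude sites are
    phenologically ahead (the usual thermal gradient).  With constant
    altitudes or a constant map the correlation is undefined and flagged.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    alts = np.array([p.altitude for p in points], dtype=float)
    vals = np.array([grid.value_at(p.x, p.y) for p in points], dtype=float)
    if np.ptp(alts) == 0 or np.ptp(vals) == 0:
        return float("nan"), False
    rho = spearmanr(alts, vals).statistic
    return float(rho), bool(np.isfinite(rho))
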