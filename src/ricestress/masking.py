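"""Terrain and cloud screening.

Rice paddies are confined to near-flat terrain, so pixels whose slope
exceeds a threshold (default 8 degrees) are removed before classification.
Slope is computed from the DEM with Horn's eight-neighbor method, the
de-facto GIS standard. Cloud-contaminated observations are invalidated per
(pixel, date) from the QA flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .spectral_indices import IndexStack
from .synthetic_scene import DemRaster

DEFAULT_SLOPE_THRESHOLD_DEG = 8.0


@dataclass
class SlopeRaster:
    """Slope in degrees per pixel, in [0, 90)."""

    slope_deg: np.ndarray


def compute_slope(dem: DemRaster) -> SlopeRaster:
    """Horn's eight-neighbor finite-difference slope in degrees.

    Edge pixels use replicated-border neighbors. Requires at least a 3x3
    grid and a positive cell size.
    """
    z = np.asarray(dem.elevation, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 pixels")
    if not dem.cell_size > 0:
        raise ValueError("cell_size must be positive")
    zp = np.pad(z, 1, mode="edge")
    # Neighbors of each cell: compass notation on the padded array.
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dem.cell_size)
    gy = ((sw + 2 * s_ + se) - (nw + 2 * n_ + ne)) / (8.0 * dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return SlopeRaster(slope_deg=slope)


def slope_mask(slope: SlopeRaster,
               threshold_deg: float = DEFAULT_SLOPE_THRESHOLD_DEG) -> np.ndarray:
    """Boolean pixel mask: True where slope <= threshold (rice-plausible).

    Pixels with slope strictly greater than the threshold are removed; a
    pixel at exactly the threshold is retained.
    """
    if threshold_deg < 0:
        raise ValueError("threshold_deg must be nonnegative")
    return slope.slope_deg <= threshold_deg


def apply_cloud_mask(indices: IndexStack, qa: np.ndarray) -> IndexStack:
    """Invalidate all index cells at cloud-flagged (pixel, date) positions.

    ``qa`` is True for valid observations. Idempotent; returns a new stack.
    """
    qa = np.asarray(qa, dtype=bool)
    if qa.shape != (indices.n_dates,) + indices.shape:
        raise ValueError(
            f"QA shape {qa.shape} does not match index grid "
            f"{(indices.n_dates,) + indices.shape}"
        )
    valid = indices.valid & qa[:, None, :, :]
    values = indices.values.copy()
    values[~valid] = np.nan
    return dataclasses.replace(indices, values=values, valid=valid)
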