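"""Structural morphometrics of biofilm surface DEMs.

Implements the landscape descriptors computed per region and in a moving
window along the shear gradient: biovolume, substrate coverage, height
statistics, envelope porosity and gray-level co-occurrence (Haralick)
textural correlation, a proxy for biomass aggregation.

Regions are half-open pixel rectangles ``(row0, row1, col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dem_io import DEMGrid
from .exceptions import GeometryError, ValidationError
from .hydraulics import HydraulicProfile

#: Default detection threshold (mm): ~5 height quanta, above quantization
#: noise yet far below the <100 um colonies it must retain.
DEFAULT_H_MIN = 0.010

#: Standard unit-distance GLCM offsets (row, col): E, S, SE, NE neighbours.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_GLCM_LEVELS = 64

Region = tuple[int, int, int, int]


def _region_view(grid: DEMGrid | np.ndarray, region: Region | None) -> np.ndarray:
    h = grid.heights if isinstance(grid, DEMGrid) else np.asarray(grid, dtype=float)
    if region is None:
        region = (0, h.shape[0], 0, h.shape[1])
    r0, r1, c0, c1 = region
    if not (0 <= r0 < r1 <= h.shape[0] and 0 <= c0 < c1 <= h.shape[1]):
        raise GeometryError(f"region {region} empty or outside grid {h.shape}")
    return h[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def biovolume(grid: DEMGrid, region: Region | None = None) -> float:
    """Integrated biofilm volume (mm^3): sum of heights times pixel area."""
    view = _region_view(grid, region)
    return float(view.sum() * grid.pixel_size_mm ** 2)


def coverage(grid: DEMGrid, region: Region | None = None,
             h_min: float = DEFAULT_H_MIN) -> float:
    """Fraction of region pixels with height >= the detection threshold."""
    if h_min < 0:
        raise ValidationError("h_min must be >= 0")
    view = _region_view(grid, region)
    return float((view >= h_min).mean())


@dataclass
class HeightStats:
    mean_thickness: float  # mean over covered pixels (mm)
    max_height: float
    p99_height: float
    covered: bool


def height_stats(grid: DEMGrid, region: Region | None = None,
                 h_min: float = DEFAULT_H_MIN) -> HeightStats:
    """Thickness statistics over covered pixels; zeros if nothing covered."""
    view = _region_view(grid, region)
    cov = view[view >= h_min]
    if cov.size == 0:
        return HeightStats(0.0, 0.0, 0.0, covered=False)
    return HeightStats(
        mean_thickness=float(cov.mean()),
        max_height=float(cov.max()),
        p99_height=float(np.percentile(cov, 99)),
        covered=True,
    )


def porosity(grid: DEMGrid, region: Region | None = None,
             h_min: float = DEFAULT_H_MIN) -> float:
    """Void fraction of the envelope box bounded by the 99th-percentile height.

    porosity = 1 - volume / (region_area * p99_height). An uncovered region
    is all void (porosity 1) by convention; a space-filling slab gives 0.
    The result is clipped to [0, 1] (extremely top-heavy distributions can
    push the raw ratio above 1).
    """
    view = _region_view(grid, region)
    stats = height_stats(grid, region, h_min)
    if not stats.covered or stats.p99_height <= 0:
        return 1.0
    area = view.size * grid.pixel_size_mm ** 2
    vol = float(view.sum() * grid.pixel_size_mm ** 2)
    return float(np.clip(1.0 - vol / (area * stats.p99_height), 0.0, 1.0))


# ---------------------------------------------------------------------------
# gray-level co-occurrence correlation
# ---------------------------------------------------------------------------

def quantize_levels(view: np.ndarray, n_levels: int) -> np.ndarray | None:
    """Quantize heights to ``n_levels`` gray levels over [0, max].

    Returns None when the region maximum is 0 (no texture to quantize).
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    hmax = float(view.max())
    if hmax <= 0:
        return None
    lv = np.floor(view / hmax * n_levels).astype(np.intp)
    return np.minimum(lv, n_levels - 1)


def cooccurrence_matrix(levels: np.ndarray, offset: tuple[int, int],
                        n_levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one pixel offset."""
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ValidationError("offset must be non-zero")
    nr, nc = levels.shape
    if abs(dr) >= nr or abs(dc) >= nc:
        raise GeometryError(f"region {levels.shape} smaller than offset {offset}")
    a = levels[max(0, -dr):nr - max(0, dr), max(0, -dc):nc - max(0, dc)]
    b = levels[max(0, dr):nr + min(0, dr), max(0, dc):nc + min(0, dc)]
    counts = np.bincount((a.ravel() * n_levels + b.ravel()),
                         minlength=n_levels * n_levels)
    m = counts.reshape(n_levels, n_levels).astype(float)
    m = m + m.T  # symmetric: count each pair in both directions
    return m / m.sum()


def _haralick_correlation(p: np.ndarray) -> float:
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    pi = p.sum(axis=1)  # symmetric matrix: row and column marginals equal
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var <= 0:
        return np.nan
    cov = float(((i[:, None] - mu) * (i[None, :] - mu) * p).sum())
    return cov / var


def glcm_correlation(grid: DEMGrid | np.ndarray, region: Region | None = None,
                     n_levels: int = DEFAULT_GLCM_LEVELS,
                     offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS) -> float:
    """Mean Haralick correlation of the co-occurrence matrix over offsets.

    Heights are quantized to ``n_levels`` over [0, region max]. Returns NaN
    (the undefined marker) for constant regions, where the correlation's
    variance normalizer vanishes.
    """
    view = _region_view(grid, region)
    levels = quantize_levels(view, n_levels)
    if levels is None:
        return np.nan
    vals = [_haralick_correlation(cooccurrence_matrix(levels, off, n_levels))
            for off in offsets]
    vals = np.asarray(vals, dtype=float)
    if np.all(np.isnan(vals)):
        return np.nan
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# moving window
# ---------------------------------------------------------------------------

def moving_window_metrics(grid: DEMGrid,
                          profile: HydraulicProfile | None = None,
                          window_mm: float = 24.0,
                          step_mm: float = 2.0,
                          h_min: float = DEFAULT_H_MIN,
                          earlier: DEMGrid | None = None,
                          n_levels: int = DEFAULT_GLCM_LEVELS,
                          offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
                          ) -> pd.DataFrame:
    """All landscape metrics in a square moving window along the gradient.

    The window is ``window_mm`` on edge; when the grid's cross-flume extent
    exceeds the window edge, a centered cross-flume band of window height is
    used, so each window is square. Bed shear stress is interpolated from
    ``profile`` at the window center. If ``earlier`` (an earlier-day DEM of
    the same geometry) is given, a per-window accrual rate (mm^3/day) is
    added.
    """
    px = grid.pixel_size_mm
    win = int(round(window_mm / px))
    step = max(1, int(round(step_mm / px)))
    if win < 2:
        raise ValidationError("window too small")
    if win > grid.n_cols:
        raise GeometryError(
            f"window {window_mm} mm exceeds streamwise extent {grid.n_cols * px} mm"
        )
    if earlier is not None:
        if not grid.same_geometry(earlier):
            raise GeometryError("earlier grid geometry mismatch")
        if earlier.day >= grid.day:
            raise ValidationError("'earlier' grid must have an earlier day")

    rows_available = grid.n_rows
    band = min(win, rows_available)
    r0 = (rows_available - band) // 2
    r1 = r0 + band

    records = []
    for c0 in range(0, grid.n_cols - win + 1, step):
        region = (r0, r1, c0, c0 + win)
        center_x = grid.x_origin_m + (c0 + win / 2.0) * px * 1e-3
        stats = height_stats(grid, region, h_min)
        rec = {
            "center_x_m": center_x,
            "tau_Pa": float(profile.tau_at(center_x)) if profile is not None else np.nan,
            "volume_mm3": biovolume(grid, region),
            "coverage": coverage(grid, region, h_min),
            "mean_thickness_mm": stats.mean_thickness,
            "max_height_mm": stats.max_height,
            "p99_height_mm": stats.p99_height,
            "porosity": porosity(grid, region, h_min),
            "textural_correlation": glcm_correlation(grid, region, n_levels, offsets),
        }
        if earlier is not None:
            dv = biovolume(grid, region) - biovolume(earlier, region)
            rec["accrual_rate_mm3_day"] = dv / (grid.day - earlier.day)
        records.append(rec)
    return pd.DataFrame.from_records(records)
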