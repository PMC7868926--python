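"""Cluster/trough segmentation of biofilm landscapes.

Pixels are classified by their deviation from the local average thickness:
protruding clusters are at least ``k_hi`` times taller than the local mean,
troughs at least ``k_lo`` times lower, the remainder is base biofilm.
Uncolonized substrate (below the detection threshold) is kept as its own
``bare`` class so trough fractions are not inflated by bare plexiglass;
a merged trough+bare fraction is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .dem_io import DEMGrid
from .exceptions import GeometryError, ValidationError
from .landscape_metrics import DEFAULT_H_MIN

CLASS_BARE, CLASS_TROUGH, CLASS_BASE, CLASS_CLUSTER = 0, 1, 2, 3
CLASS_NAMES = {CLASS_BARE: "bare", CLASS_TROUGH: "trough",
               CLASS_BASE: "base", CLASS_CLUSTER: "cluster"}

#: Default local-averaging window (mm); the moving-window edge length is the
#: only landscape length scale the analysis defines.
DEFAULT_LOCAL_WINDOW_MM = 24.0
#: Minimum retained cluster footprint (mm^2), below the <100 um colony scale.
DEFAULT_MIN_AREA_MM2 = 0.01

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def local_mean(heights: np.ndarray, win_px: int) -> np.ndarray:
    """Edge-clipped box average of the landscape height.

    Each pixel gets the mean height over the ``win_px`` x ``win_px`` window
    centered on it, intersected with the grid (windows shrink at edges);
    zero-height pixels count toward the mean (the local average of the
    landscape, not of covered area).
    """
    if win_px < 1:
        raise ValidationError("window must be >= 1 px")
    pad = win_px // 2
    lo, hi = pad, win_px - pad  # rows in [i-lo, i+hi) intersected with grid
    nr, nc = heights.shape
    # integral image with a zero border
    s = np.zeros((nr + 1, nc + 1))
    np.cumsum(heights, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    r0 = np.clip(np.arange(nr) - lo, 0, nr)
    r1 = np.clip(np.arange(nr) + hi, 0, nr)
    c0 = np.clip(np.arange(nc) - lo, 0, nc)
    c1 = np.clip(np.arange(nc) + hi, 0, nc)
    total = (s[r1[:, None], c1[None, :]] - s[r0[:, None], c1[None, :]]
             - s[r1[:, None], c0[None, :]] + s[r0[:, None], c0[None, :]])
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return total / counts


@dataclass
class SegmentationMap:
    """Per-pixel class labels plus the local mean they were derived from."""

    labels: np.ndarray  # uint8, CLASS_* codes
    local_mean: np.ndarray  # mm
    parameters: dict = field(default_factory=dict)

    def fractions(self) -> dict[str, float]:
        n = self.labels.size
        out = {f"f_{name}": float((self.labels == code).sum()) / n
               for code, name in CLASS_NAMES.items()}
        out["f_trough_incl_bare"] = out["f_trough"] + out["f_bare"]
        return out


def segment_landscape(grid: DEMGrid,
                      local_window_mm: float = DEFAULT_LOCAL_WINDOW_MM,
                      k_hi: float = 2.0, k_lo: float = 2.0,
                      h_min: float = DEFAULT_H_MIN,
                      ) -> tuple[SegmentationMap, dict[str, float]]:
    """Classify pixels into bare / trough / base / cluster.

    Rules, applied in order to height h with local mean m:
    bare if h < h_min; cluster if h >= k_hi * m; trough if h <= m / k_lo;
    else base. Class fractions sum to 1. Thresholds are relative, so the
    segmentation is invariant to rescaling heights and h_min together.
    """
    if k_hi <= 1 or k_lo <= 1:
        raise ValidationError("k_hi and k_lo must exceed 1")
    px = grid.pixel_size_mm
    win_px = int(round(local_window_mm / px))
    if win_px < 10:
        raise ValidationError("local window must span at least 10 pixels")
    if win_px > max(grid.n_rows, grid.n_cols):
        raise GeometryError("local window exceeds the grid extent")

    h = grid.heights
    m = local_mean(h, win_px)
    labels = np.full(h.shape, CLASS_BASE, dtype=np.uint8)
    labels[h <= m / k_lo] = CLASS_TROUGH
    labels[h >= k_hi * m] = CLASS_CLUSTER
    labels[h < h_min] = CLASS_BARE

    segmap = SegmentationMap(
        labels=labels, local_mean=m,
        parameters={"local_window_mm": local_window_mm, "k_hi": k_hi,
                    "k_lo": k_lo, "h_min": h_min},
    )
    return segmap, segmap.fractions()


def extract_clusters(segmap: SegmentationMap, grid: DEMGrid,
                     min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected cluster objects (8-connectivity) with per-cluster morphology.

    Returns a table of cluster statistics (one row per retained component)
    and the labeled raster. Components smaller than ``min_area_mm2`` are
    treated as speckle and dropped (their raster labels are zeroed too).
    """
    if segmap.labels.shape != grid.heights.shape:
        raise GeometryError("segmentation map does not match the grid")
    px = grid.pixel_size_mm
    labeled, _ = ndimage.label(segmap.labels == CLASS_CLUSTER, structure=_EIGHT_CONN)
    rows = []
    for prop in regionprops(labeled, intensity_image=grid.heights):
        area = prop.area * px ** 2
        if area < min_area_mm2:
            labeled[labeled == prop.label] = 0
            continue
        r0, c0, r1, c1 = prop.bbox
        length_flow = (c1 - c0) * px
        width_cross = (r1 - r0) * px
        max_h = float(prop.image_intensity[prop.image].max())
        eq_diam = prop.equivalent_diameter_area * px
        rows.append({
            "id": prop.label,
            "area_mm2": area,
            "volume_mm3": float(prop.image_intensity[prop.image].sum()) * px ** 2,
            "max_height_mm": max_h,
            "equivalent_diameter_mm": eq_diam,
            "length_flow_mm": length_flow,
            "width_cross_mm": width_cross,
            "vertical_aspect": max_h / eq_diam,
            "horizontal_aspect": length_flow / width_cross,
            "centroid_x_m": grid.x_origin_m + (prop.centroid[1] + 0.5) * px * 1e-3,
            "centroid_y_mm": (prop.centroid[0] + 0.5) * px,
        })
    stats = pd.DataFrame.from_records(
        rows, columns=["id", "area_mm2", "volume_mm3", "max_height_mm",
                       "equivalent_diameter_mm", "length_flow_mm",
                       "width_cross_mm", "vertical_aspect",
                       "horizontal_aspect", "centroid_x_m", "centroid_y_mm"])
    return stats, labeled


def cluster_volume_cdf(stats: pd.DataFrame) -> pd.DataFrame:
    """Cumulative cluster-size distribution: count of clusters <= each volume."""
    v = np.sort(stats["volume_mm3"].to_numpy()) if len(stats) else np.array([])
    return pd.DataFrame({"volume_mm3": v,
                         "cumulative_count": np.arange(1, len(v) + 1)})
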