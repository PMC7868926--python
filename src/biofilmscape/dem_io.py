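"""Reading, writing and validating biofilm surface DEMs.

A DEM (digital elevation model) is a 2D raster whose pixel values encode
local biofilm thickness above the substrate. Heights are held in memory as
floating-point millimetres; on disk they are 16-bit gray levels in units of
the OCT height quantum (2.18 um by default), following the convention that
biofilm thickness is encoded as pixel gray level. Rows run cross-flume (y),
columns run streamwise (x), with column 0 at ``x_origin_m`` and x increasing
in the flow direction; pixel centers sit at ``(i + 0.5) * pixel_size``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import GeometryError, ValidationError

#: Default pixel edge length (mm): 40 um OCT lateral resolution.
DEFAULT_PIXEL_SIZE_MM = 0.040
#: Default height quantization step (mm): 2.18 um OCT axial resolution.
DEFAULT_Z_QUANTUM_MM = 0.00218
#: Approximate OCT imaging ceiling (mm); taller structures are clipped.
DEFAULT_CLIP_MM = 1.2

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class DEMGrid:
    """Single-day biofilm surface DEM with acquisition metadata.

    Parameters
    ----------
    heights
        2D array of biofilm thickness in mm, all values >= 0.
    pixel_size_mm
        Lateral pixel edge length in mm (same in x and y).
    z_quantum_mm
        Height quantization step in mm.
    x_origin_m
        Streamwise (along-flume) position of the first column, in metres.
    day
        Acquisition day (>= 0).
    flume_id
        Replicate flume identifier.
    clip_mm
        Device imaging ceiling; heights at/above this value are flagged as
        potentially clipped (they remain valid heights).
    """

    heights: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    z_quantum_mm: float = DEFAULT_Z_QUANTUM_MM
    x_origin_m: float = 0.0
    day: int = 0
    flume_id: str = "I"
    clip_mm: float = DEFAULT_CLIP_MM

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValidationError("DEM heights must be a non-empty 2D array")
        if self.pixel_size_mm <= 0:
            raise ValidationError("pixel_size_mm must be positive")
        if self.z_quantum_mm <= 0:
            raise ValidationError("z_quantum_mm must be positive")
        if self.day < 0:
            raise ValidationError("day must be >= 0")
        neg = np.argwhere(self.heights < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative height {self.heights[r, c]:g} mm at row {r}, col {c}"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.heights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.heights.shape[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(cross-flume, streamwise) extent in mm."""
        return (self.n_rows * self.pixel_size_mm, self.n_cols * self.pixel_size_mm)

    def x_centers_m(self) -> np.ndarray:
        """Streamwise coordinate (m) of each column's pixel center."""
        j = np.arange(self.n_cols)
        return self.x_origin_m + (j + 0.5) * self.pixel_size_mm * 1e-3

    # -- measurement diagnostics ------------------------------------------
    def clip_mask(self) -> np.ndarray:
        """Boolean mask of pixels at/above the imaging ceiling."""
        return self.heights >= self.clip_mm - 0.5 * self.z_quantum_mm

    def clipped_fraction(self) -> float:
        return float(self.clip_mask().mean())

    def quantized(self) -> "DEMGrid":
        """Copy with heights rounded to integer multiples of the quantum."""
        q = self.z_quantum_mm
        return replace(self, heights=np.round(self.heights / q) * q)

    def same_geometry(self, other: "DEMGrid") -> bool:
        return (
            self.heights.shape == other.heights.shape
            and np.isclose(self.pixel_size_mm, other.pixel_size_mm)
            and np.isclose(self.x_origin_m, other.x_origin_m)
        )


@dataclass
class DEMSeries:
    """Time-ordered DEM acquisitions of one flume position."""

    grids: list[DEMGrid] = field(default_factory=list)
    alignment: str = "assumed-aligned"

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValidationError("DEMSeries needs at least one grid")
        days = [g.day for g in self.grids]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValidationError(f"days must be strictly increasing, got {days}")
        first = self.grids[0]
        for g in self.grids[1:]:
            if not first.same_geometry(g):
                raise GeometryError(
                    f"grid geometry mismatch between day {first.day} "
                    f"{first.heights.shape} and day {g.day} {g.heights.shape}"
                )

    @property
    def days(self) -> list[int]:
        return [g.day for g in self.grids]

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(self.grids)


# ---------------------------------------------------------------------------
# metadata sidecars
# ---------------------------------------------------------------------------

def _meta_from_mapping(meta: Mapping | None) -> dict:
    """Normalize sidecar/manifest metadata keys to DEMGrid kwargs."""
    meta = dict(meta or {})
    out: dict = {}
    if "pixel_size_um" in meta:
        out["pixel_size_mm"] = float(meta["pixel_size_um"]) * 1e-3
    if "pixel_size_mm" in meta:
        out["pixel_size_mm"] = float(meta["pixel_size_mm"])
    if "z_quantum_um" in meta:
        out["z_quantum_mm"] = float(meta["z_quantum_um"]) * 1e-3
    if "z_quantum_mm" in meta:
        out["z_quantum_mm"] = float(meta["z_quantum_mm"])
    for key in ("x_origin_m", "clip_mm"):
        if key in meta:
            out[key] = float(meta[key])
    if "day" in meta:
        out["day"] = int(meta["day"])
    if "flume_id" in meta:
        out["flume_id"] = str(meta["flume_id"])
    return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _write_sidecar(grid: DEMGrid, path: Path) -> None:
    meta = {
        "pixel_size_um": grid.pixel_size_mm * 1e3,
        "z_quantum_um": grid.z_quantum_mm * 1e3,
        "x_origin_m": grid.x_origin_m,
        "day": grid.day,
        "flume_id": grid.flume_id,
        "clip_mm": grid.clip_mm,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_dem(path: str | os.PathLike, meta: Mapping | None = None) -> DEMGrid:
    """Read a DEM from a 16-bit grayscale TIFF or a delimited text grid.

    TIFF pixel values are gray levels in units of the height quantum and are
    converted to mm; text grids already hold mm. Metadata is resolved from a
    ``<file>.yaml`` sidecar if present, then overridden by ``meta``.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"DEM file not found: {path}")

    kwargs: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.is_file():
        kwargs.update(_meta_from_mapping(yaml.safe_load(sidecar.read_text())))
    kwargs.update(_meta_from_mapping(meta))

    if path.suffix.lower() in _TIFF_SUFFIXES:
        raw = tifffile.imread(path)
        if raw.ndim != 2:
            raise ValidationError(f"expected 2D grayscale TIFF, got shape {raw.shape}")
        q = kwargs.get("z_quantum_mm", DEFAULT_Z_QUANTUM_MM)
        heights = raw.astype(float) * q
    else:
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        try:
            heights = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise IOError(f"cannot parse text DEM {path}: {exc}") from exc
        neg = np.argwhere(heights < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"{path}: negative height {heights[r, c]:g} at row {r}, col {c}"
            )
    return DEMGrid(heights=heights, **kwargs)


def write_dem(grid: DEMGrid, path: str | os.PathLike) -> None:
    """Write a DEM plus YAML metadata sidecar.

    TIFF output stores 16-bit gray levels in quantum units (lossy only below
    half a quantum); text output stores mm values at full float precision.
    """
    path = Path(path)
    if path.is_dir():
        raise IOError(f"refusing to write DEM onto a directory: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        levels = np.round(grid.heights / grid.z_quantum_mm)
        if levels.max() > np.iinfo(np.uint16).max:
            raise ValidationError(
                "heights exceed the 16-bit gray-level range at this z_quantum"
            )
        tifffile.imwrite(path, levels.astype(np.uint16))
    else:
        np.savetxt(path, grid.heights, fmt="%.9g", delimiter=",")
    _write_sidecar(grid, path)


# ---------------------------------------------------------------------------
# series loading
# ---------------------------------------------------------------------------

def load_series(manifest: str | os.PathLike | pd.DataFrame) -> DEMSeries:
    """Load a day-ordered DEM series from a manifest.

    The manifest is a CSV (or DataFrame) with columns ``path, day`` and
    optionally ``flume_id, x_origin_m``; relative paths are resolved against
    the manifest location. Grids are sorted by day; duplicate days and
    geometry mismatches are rejected.
    """
    if isinstance(manifest, pd.DataFrame):
        table = manifest.copy()
        base = Path(".")
    else:
        mpath = Path(manifest)
        table = pd.read_csv(mpath)
        base = mpath.parent
    if "path" not in table.columns or "day" not in table.columns:
        raise ValidationError("manifest needs 'path' and 'day' columns")
    if table.empty:
        raise ValidationError("manifest is empty")
    days = table["day"].astype(int)
    if days.duplicated().any():
        dup = sorted(days[days.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate acquisition days in manifest: {dup}")

    grids = []
    for _, row in table.sort_values("day").iterrows():
        meta = {k: row[k] for k in ("flume_id", "x_origin_m") if k in row and pd.notna(row[k])}
        meta["day"] = int(row["day"])
        p = Path(row["path"])
        grids.append(read_dem(p if p.is_absolute() else base / p, meta=meta))
    return DEMSeries(grids=grids)


def write_series(series: DEMSeries, directory: str | os.PathLike,
                 fmt: str = "tif") -> Path:
    """Write every grid of a series plus a manifest CSV; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in series:
        name = f"dem_flume{g.flume_id}_day{g.day:02d}.{fmt}"
        write_dem(g, directory / name)
        rows.append(
            {"path": name, "day": g.day, "flume_id": g.flume_id,
             "x_origin_m": g.x_origin_m}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
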