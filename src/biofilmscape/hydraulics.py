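"""Hydraulic descriptors along the flume.

The flume narrows in the flow direction, so mean velocity, bed shear stress
and Reynolds number all increase streamwise. The spatially resolved profile
comes from an external CFD run and is consumed here as a table; this module
only interpolates it and provides analytic open-channel helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RangeError, ValidationError

PROFILE_COLUMNS = ["x_m", "U_m_s", "tau_Pa", "Re"]


@dataclass
class HydraulicProfile:
    """Tabulated streamwise position -> (mean velocity, bed shear, Re)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"hydraulic profile missing columns {missing}")
        t = self.table[PROFILE_COLUMNS].astype(float).reset_index(drop=True)
        x = t["x_m"].to_numpy()
        if len(x) < 2:
            raise ValidationError("hydraulic profile needs >= 2 rows")
        if not np.all(np.diff(x) > 0):
            raise ValidationError("x_m must be strictly increasing")
        if (t[["U_m_s", "tau_Pa", "Re"]].to_numpy() < 0).any():
            raise ValidationError("U, tau and Re must be non-negative")
        # For this flume geometry shear and Re grow downstream; a violation
        # hints at a malformed table but is not fatal.
        for col in ("tau_Pa", "Re"):
            if np.any(np.diff(t[col].to_numpy()) < 0):
                warnings.warn(f"hydraulic profile: {col} is not non-decreasing in x",
                              stacklevel=2)
        self.table = t

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "HydraulicProfile":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(Path(path), index=False)

    # -- lookup -----------------------------------------------------------
    @property
    def x_range(self) -> tuple[float, float]:
        x = self.table["x_m"].to_numpy()
        return float(x[0]), float(x[-1])

    def lookup(self, x) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linearly interpolate (U, tau, Re) at streamwise position(s) x (m).

        Exact at table nodes; no extrapolation — x outside the tabulated
        range raises :class:`RangeError`.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if np.any(x < lo) or np.any(x > hi):
            raise RangeError(
                f"position {x[(x < lo) | (x > hi)].ravel()[:1]} m outside "
                f"tabulated range [{lo:g}, {hi:g}] m"
            )
        xs = self.table["x_m"].to_numpy()
        vals = tuple(
            np.interp(x, xs, self.table[c].to_numpy())
            for c in ("U_m_s", "tau_Pa", "Re")
        )
        return vals

    def tau_at(self, x) -> np.ndarray:
        return self.lookup(x)[1]


def shear_profile_lookup(profile: HydraulicProfile, x):
    """Functional alias for :meth:`HydraulicProfile.lookup`."""
    return profile.lookup(x)


def open_channel_numbers(U: float, width: float, depth: float,
                         nu: float = 1.0e-6, mu: float = 1.0e-3,
                         re_factor: float = 1.0) -> tuple[float, float]:
    """Analytic open-channel Reynolds number and laminar bed-shear estimate.

    Re = re_factor * U * R_h / nu with hydraulic radius
    R_h = width*depth / (width + 2*depth); some conventions use 4*R_h as the
    length scale, hence the configurable factor (default 1).
    tau = 3 * mu * U / depth is the plane-laminar wall shear of a parabolic
    profile — a rough stand-in for a resolved CFD bed shear.
    """
    if min(U, width, depth, nu, mu) <= 0:
        raise ValidationError("open_channel_numbers requires positive inputs")
    r_h = width * depth / (width + 2.0 * depth)
    re = re_factor * U * r_h / nu
    tau_laminar = 3.0 * mu * U / depth
    return re, tau_laminar
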