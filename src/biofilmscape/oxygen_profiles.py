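"""Oxygen microprofile parsing and statistics.

Microsensor profiles record dissolved oxygen (umol/L) versus depth (mm,
relative to the biofilm surface; negative depths are in the water above).
The module aligns profiles to the surface, computes local concentration
gradients over a fixed depth window, forms the light:dark gradient ratio
(a proxy for net autotrophic vs heterotrophic aerial oxygen flux), and runs
the variance-heterogeneity and depth-binned location tests used to compare
morphotypes and wall-vs-core positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

#: Depth window (mm) for local gradients near the biofilm surface.
GRADIENT_WINDOW_MM = (0.05, 0.15)

_CSV_COLUMNS = ["profile_id", "depth_mm", "O2_umol_L", "condition",
                "morphotype", "wall_distance_mm"]


@dataclass
class OxygenProfile:
    """One depth-resolved oxygen concentration series."""

    depths: np.ndarray  # mm relative to biofilm surface
    concentrations: np.ndarray  # umol/L
    condition: str  # 'light' | 'dark'
    morphotype: str  # 'SFM' | 'FFM'
    profile_id: str
    wall_distance_mm: float | None = None  # distance from nearest cluster wall

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.shape != self.concentrations.shape or self.depths.ndim != 1:
            raise ValidationError("depths/concentrations must be matching 1D arrays")
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError(
                f"profile {self.profile_id}: depths must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValidationError(
                f"profile {self.profile_id}: negative concentration")
        if self.condition not in ("light", "dark"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not self.morphotype:
            raise ValidationError("morphotype must be set")

    def rezeroed(self, surface_z_mm: float) -> "OxygenProfile":
        """Shift the depth axis so the stated surface position becomes 0."""
        return replace(self, depths=self.depths - surface_z_mm)


@dataclass
class OxygenProfileSet:
    profiles: list[OxygenProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def select(self, condition: str | None = None, morphotype: str | None = None,
               wall_max_mm: float | None = None, wall_min_mm: float | None = None,
               ) -> "OxygenProfileSet":
        out = self.profiles
        if condition is not None:
            out = [p for p in out if p.condition == condition]
        if morphotype is not None:
            out = [p for p in out if p.morphotype == morphotype]
        if wall_max_mm is not None:
            out = [p for p in out if p.wall_distance_mm is not None
                   and p.wall_distance_mm <= wall_max_mm]
        if wall_min_mm is not None:
            out = [p for p in out if p.wall_distance_mm is not None
                   and p.wall_distance_mm >= wall_min_mm]
        return OxygenProfileSet(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            for z, c in zip(p.depths, p.concentrations):
                rows.append({"profile_id": p.profile_id, "depth_mm": z,
                             "O2_umol_L": c, "condition": p.condition,
                             "morphotype": p.morphotype,
                             "wall_distance_mm": p.wall_distance_mm})
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OxygenProfileSet":
        required = {"profile_id", "depth_mm", "O2_umol_L", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"oxygen table missing columns {sorted(missing)}")
        profiles = []
        for (pid, cond), sub in df.groupby(["profile_id", "condition"], sort=True):
            wall = sub["wall_distance_mm"].iloc[0] if "wall_distance_mm" in sub else None
            profiles.append(OxygenProfile(
                depths=sub["depth_mm"].to_numpy(),
                concentrations=sub["O2_umol_L"].to_numpy(),
                condition=str(cond),
                morphotype=str(sub["morphotype"].iloc[0]) if "morphotype" in sub else "",
                profile_id=str(pid),
                wall_distance_mm=None if wall is None or pd.isna(wall) else float(wall),
            ))
        return cls(profiles)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def parse_profiles(path_or_df, surface_z: dict[str, float] | None = None,
                   ) -> OxygenProfileSet:
    """Read an oxygen profile CSV; optionally re-zero depths per profile.

    ``surface_z`` maps profile_id to the depth (mm, original axis) of the
    biofilm surface; matching profiles are shifted so the surface is at 0.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    pset = OxygenProfileSet.from_frame(df)
    if surface_z:
        pset = OxygenProfileSet([
            p.rezeroed(surface_z[p.profile_id]) if p.profile_id in surface_z else p
            for p in pset
        ])
    return pset


def estimate_surface(profile: OxygenProfile) -> float:
    """Depth of steepest concentration change (max |dC/dz|), a surface proxy
    for dark profiles when no measured surface position is available."""
    dz = np.gradient(profile.concentrations, profile.depths)
    return float(profile.depths[int(np.argmax(np.abs(dz)))])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def local_gradient(profile: OxygenProfile,
                   z1: float = GRADIENT_WINDOW_MM[0],
                   z2: float = GRADIENT_WINDOW_MM[1],
                   method: str = "ols") -> float:
    """Concentration gradient (umol/L per mm) over the depth window [z1, z2].

    Default is the OLS slope over all samples in the window (robust to
    sensor noise); ``method='two-point'`` uses the endpoints only.
    """
    sel = (profile.depths >= z1) & (profile.depths <= z2)
    z, c = profile.depths[sel], profile.concentrations[sel]
    if len(z) < 2:
        raise ValidationError(
            f"profile {profile.profile_id}: <2 samples in [{z1}, {z2}] mm")
    if method == "two-point":
        return float((c[-1] - c[0]) / (z[-1] - z[0]))
    return float(np.polyfit(z, c, 1)[0])


def light_dark_ratio(light: OxygenProfile, dark: OxygenProfile,
                     z1: float = GRADIENT_WINDOW_MM[0],
                     z2: float = GRADIENT_WINDOW_MM[1]) -> float:
    """|light gradient| / |dark gradient| at one location; NaN if the dark
    gradient vanishes. Scale-invariant in the concentrations."""
    if light.profile_id != dark.profile_id:
        raise ValidationError(
            f"mismatched locations: {light.profile_id} vs {dark.profile_id}")
    if light.condition != "light" or dark.condition != "dark":
        raise ValidationError("pass (light, dark) profiles in that order")
    g_l = local_gradient(light, z1, z2)
    g_d = local_gradient(dark, z1, z2)
    if abs(g_d) < 1e-9:  # flat dark profile: ratio undefined
        return np.nan
    return abs(g_l) / abs(g_d)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def brown_forsythe_test(*groups) -> tuple[float, float]:
    """Brown–Forsythe Levene-type test of variance heterogeneity.

    ANOVA on absolute deviations from the group medians; robust to
    non-normality. Returns (W, p) with p from F(k-1, N-k). Degenerate input
    (all deviations equal) gives (0, 1).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    z = [np.abs(g - np.median(g)) for g in groups]
    if np.ptp(np.concatenate(z)) == 0:
        return 0.0, 1.0
    w, p = sps.levene(*groups, center="median")
    return float(w), float(p)


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p).

    Zero variance in both samples with equal means gives (0, n-2, 1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf, float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / len(a), vb / len(b)
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (len(a) - 1) + se2b ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def grouped_depth_compare(set_a: OxygenProfileSet, set_b: OxygenProfileSet,
                          bin_mm: float = 0.1, grouping: str = "depth",
                          pooling: str = "points",
                          z_min: float = 0.0, z_max: float | None = None,
                          ) -> pd.DataFrame:
    """Per-bin Welch tests between two profile sets.

    Samples are pooled into ``bin_mm`` steps of depth (or wall distance);
    each bin with >= 2 values on both sides is tested, others are skipped
    with a note. ``pooling='points'`` pools raw samples; ``'profiles'``
    first averages within each profile per bin. Benjamini–Hochberg adjusted
    q-values are added across the tested bins (raw p-values are kept too).
    """
    if grouping not in ("depth", "wall_distance"):
        raise ValidationError("grouping must be 'depth' or 'wall_distance'")

    def collect(pset: OxygenProfileSet) -> pd.DataFrame:
        df = pset.to_frame()
        if grouping == "wall_distance":
            df = df.dropna(subset=["wall_distance_mm"])
            df["coord"] = df["wall_distance_mm"]
        else:
            df["coord"] = df["depth_mm"]
        df = df[df["coord"] >= z_min]
        if z_max is not None:
            df = df[df["coord"] <= z_max]
        df["bin"] = np.floor(df["coord"] / bin_mm).astype(int)
        if pooling == "profiles":
            df = (df.groupby(["bin", "profile_id"], as_index=False)
                  .agg(O2_umol_L=("O2_umol_L", "mean")))
        return df

    da, db = collect(set_a), collect(set_b)
    bins = sorted(set(da["bin"]) | set(db["bin"]))
    rows = []
    for b in bins:
        va = da.loc[da["bin"] == b, "O2_umol_L"].to_numpy()
        vb = db.loc[db["bin"] == b, "O2_umol_L"].to_numpy()
        rec = {"bin_lo_mm": b * bin_mm, "bin_hi_mm": (b + 1) * bin_mm,
               "n_a": len(va), "n_b": len(vb),
               "mean_a": va.mean() if len(va) else np.nan,
               "mean_b": vb.mean() if len(vb) else np.nan,
               "t": np.nan, "df": np.nan, "p": np.nan, "note": "ok"}
        if len(va) < 2 or len(vb) < 2:
            rec["note"] = "skipped: n<2"
        else:
            rec["t"], rec["df"], rec["p"] = welch_test(va, vb)
        rows.append(rec)
    table = pd.DataFrame.from_records(rows)
    tested = table["note"] == "ok"
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = multipletests(
            table.loc[tested, "p"].to_numpy(), method="fdr_bh")[1]
    return table
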