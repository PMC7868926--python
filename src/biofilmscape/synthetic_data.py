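"""Ground-truthed synthetic inputs emulating the flume study.

The generator emits the same objects and on-disk formats the analysis
modules consume, with full bookkeeping of what was planted so tests can
check recovery:

* a biofilm landscape along a shear gradient — tall anisotropic Gaussian
  clusters over a patchy low floor with small colonies on the low-shear
  side (slow-flow morphotype, SFM), blending via a logistic weight in
  bed shear stress into a thin coalescent carpet (fast-flow morphotype,
  FFM) built from a thresholded correlated random field;
* 3-day-interval growth series in which cluster amplitudes grow
  exponentially and individual SFM clusters occasionally detach or are
  pushed downstream (event log recorded);
* a linear hydraulic profile spanning the study's velocity/shear/Reynolds
  ranges;
* closed-form steady-state diffusion–reaction oxygen profiles (zero-order
  consumption/production, no-flux base), with per-profile rate variability,
  sensor noise and an optional wall-replenishment term.

The measurement model mirrors the OCT artefacts: depth clipping at the
~1.2 mm imaging ceiling, then height quantization to the 2.18 um quantum.
All randomness flows through one seeded ``numpy.random.default_rng``
(PCG64), so equal seeds give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dem_io import DEMGrid, DEMSeries, DEFAULT_PIXEL_SIZE_MM, DEFAULT_Z_QUANTUM_MM, DEFAULT_CLIP_MM
from .exceptions import ValidationError
from .hydraulics import HydraulicProfile
from .oxygen_profiles import OxygenProfile, OxygenProfileSet


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class LandscapeParams:
    """Study-scale defaults for the synthetic biofilm landscape.

    Extent and resolution follow the imaged strip (0.025 m x 0.4 m at
    40 um pixels); the shear profile spans 0.04–0.13 Pa with the
    morphotype transition centered at 0.08 Pa. SFM clusters reach the
    ~1.5 mm scale (amplitude cap) with colonies <100 um between them;
    the FFM carpet is ~0.25 mm thick with ~90% coverage.
    """

    extent_m: tuple[float, float] = (0.025, 0.4)  # (cross, streamwise)
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    # hydraulic gradient
    tau_start_pa: float = 0.04
    tau_end_pa: float = 0.13
    tau_star_pa: float = 0.08  # morphotype transition shear
    logistic_width_pa: float = 0.005  # abrupt morphotype transition
    # SFM clusters
    cluster_density_mm2: float = 0.03
    cluster_amp_median_mm: float = 1.0
    cluster_amp_sigma: float = 0.4  # lognormal sigma
    amp_cap_mm: float = 1.5
    cluster_sigma_mm: tuple[float, float] = (0.3, 0.7)  # cross-flume sd range
    anisotropy: float = 1.4  # streamwise elongation of sigma_x over sigma_y
    min_separation_mm: float = 4.0  # hardcore distance between cluster centers
    edge_margin_mm: float = 3.0  # keep cluster centers clear of the strip rim
    # SFM floor and trough colonies
    floor_height_mm: float = 0.02
    floor_coverage: float = 0.45
    floor_corr_mm: float = 1.5
    colony_density_mm2: float = 0.2
    colony_amp_mm: tuple[float, float] = (0.02, 0.08)
    colony_sigma_mm: tuple[float, float] = (0.05, 0.12)
    # FFM carpet; carpet_mean_mm is the thickness at the outlet (max shear),
    # thinning toward the transition by the shear gain: biomass accrual is
    # mass-transfer limited, so the carpet keeps thickening with shear
    carpet_mean_mm: float = 0.25
    carpet_corr_mm: float = 2.0
    carpet_coverage: float = 0.92
    carpet_shear_gain: float = 2.5  # fractional thickening from tau* to outlet
    # measurement model
    noise_sigma_mm: float = 0.0
    z_quantum_mm: float = DEFAULT_Z_QUANTUM_MM
    clip_mm: float = DEFAULT_CLIP_MM

    def shape(self) -> tuple[int, int]:
        ny = int(round(self.extent_m[0] * 1e3 / self.pixel_size_mm))
        nx = int(round(self.extent_m[1] * 1e3 / self.pixel_size_mm))
        if ny < 1 or nx < 1:
            raise ValidationError(f"degenerate extent {self.extent_m}")
        return ny, nx


@dataclass
class OxygenParams:
    """Closed-form diffusion–reaction parameters for both morphotypes.

    Concentrations in umol/L, depths in mm; rd = R/D and pd = P/D in
    umol L^-1 mm^-2. Defaults put the SFM dark base concentration at
    40 umol/L and the FFM at 178 umol/L, with production balancing
    consumption (light:dark gradient ratio 1).
    """

    c0: float = 300.0  # bulk/surface oxygen
    sfm_L_mm: float = 0.5
    sfm_rd: float = 2080.0
    sfm_pd: float = 2080.0
    sfm_n: int = 35
    sfm_spread: float = 0.12  # lognormal sd of per-profile rate multiplier
    ffm_L_mm: float = 0.25
    ffm_rd: float = 3904.0
    ffm_pd: float = 3904.0
    ffm_n: int = 27
    ffm_spread: float = 0.05
    dz_mm: float = 0.025
    z_above_mm: float = 0.2
    noise_umol: float = 2.0
    dbl_mm: float = 0.0  # diffusive boundary layer thickness (none detected)
    # wall-replenishment transect (SFM, dark)
    wall_distances_mm: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
    wall_reps: int = 4
    wall_delta: float = 0.5  # fractional consumption relief at the wall
    wall_lambda_mm: float = 0.3  # decay length of the relief


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle use in tests."""

    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: list[dict] = field(default_factory=list)
    noiseless: np.ndarray | None = None
    noiseless_by_day: dict[int, np.ndarray] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    oxygen: dict = field(default_factory=dict)
    seed: int | None = None


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def ffm_weight(tau, tau_star: float, width: float) -> np.ndarray:
    """Logistic fast-flow weight in bed shear stress (0 = SFM, 1 = FFM)."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(tau, float) - tau_star) / width))


def gaussian_bump_field(shape: tuple[int, int], row: float, col: float,
                        sigma_row_px: float, sigma_col_px: float,
                        amp: float, out: np.ndarray | None = None) -> np.ndarray:
    """Add one anisotropic Gaussian cap to a field (4-sigma local patch).

    The analytic volume of the full cap is 2*pi*sigma_x*sigma_y*amp, which
    is what the ground-truth tables record.
    """
    if out is None:
        out = np.zeros(shape)
    nr, nc = shape
    r0 = max(0, int(np.floor(row - 4 * sigma_row_px)))
    r1 = min(nr, int(np.ceil(row + 4 * sigma_row_px)) + 1)
    c0 = max(0, int(np.floor(col - 4 * sigma_col_px)))
    c1 = min(nc, int(np.ceil(col + 4 * sigma_col_px)) + 1)
    if r0 >= r1 or c0 >= c1:
        return out
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    out[r0:r1, c0:c1] += amp * np.exp(
        -(rr ** 2 / (2 * sigma_row_px ** 2) + cc ** 2 / (2 * sigma_col_px ** 2)))
    return out


def _grf(shape: tuple[int, int], corr_px: float, rng: np.random.Generator,
         ) -> np.ndarray:
    """Standardized smooth Gaussian random field (unit variance)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr_px, mode="wrap")
    return (f - f.mean()) / f.std()


def _tau_per_column(p: LandscapeParams, nx: int) -> np.ndarray:
    x = (np.arange(nx) + 0.5) / nx
    return p.tau_start_pa + (p.tau_end_pa - p.tau_start_pa) * x


def _place_clusters(p: LandscapeParams, rng: np.random.Generator,
                    shape: tuple[int, int]) -> pd.DataFrame:
    """Inhomogeneous hardcore point process for SFM cluster centers.

    A Poisson draw at the nominal density is thinned by the SFM weight
    (1 - logistic FFM weight) and by a minimum-separation rule; the ground
    truth records what was actually placed.
    """
    ny, nx = shape
    px = p.pixel_size_mm
    area_mm2 = ny * nx * px ** 2
    n = rng.poisson(p.cluster_density_mm2 * area_mm2)
    margin = min(p.edge_margin_mm / px, 0.45 * min(ny, nx))
    rows = rng.uniform(margin, ny - margin, n)
    cols = rng.uniform(margin, nx - margin, n)
    keep_u = rng.random(n)
    amps = np.minimum(
        rng.lognormal(np.log(p.cluster_amp_median_mm), p.cluster_amp_sigma, n),
        p.amp_cap_mm)
    sig_y = rng.uniform(*p.cluster_sigma_mm, n)
    sig_x = sig_y * p.anisotropy

    tau = _tau_per_column(p, nx)
    w = ffm_weight(tau, p.tau_star_pa, p.logistic_width_pa)
    min_sep_px = p.min_separation_mm / px

    placed: list[dict] = []
    pr, pc = [], []
    for i in range(n):
        if keep_u[i] >= 1.0 - w[int(cols[i])]:
            continue  # thinned: FFM side
        if placed:
            d2 = (np.array(pr) - rows[i]) ** 2 + (np.array(pc) - cols[i]) ** 2
            if d2.min() < min_sep_px ** 2:
                continue  # hardcore rejection
        pr.append(rows[i])
        pc.append(cols[i])
        placed.append({
            "id": len(placed), "row": rows[i], "col": cols[i],
            "y_mm": (rows[i] + 0.5) * px,
            "x_m": (cols[i] + 0.5) * px * 1e-3,
            "sigma_x_mm": sig_x[i], "sigma_y_mm": sig_y[i],
            "amp_mm": amps[i],
            "volume_mm3": 2 * np.pi * sig_x[i] * sig_y[i] * amps[i],
        })
    return pd.DataFrame.from_records(
        placed, columns=["id", "row", "col", "y_mm", "x_m", "sigma_x_mm",
                         "sigma_y_mm", "amp_mm", "volume_mm3"])


def _carpet_gain(p: LandscapeParams, tau: np.ndarray) -> np.ndarray:
    """Shear-dependent carpet thickness factor: 1 at the outlet, falling to
    1/(1+gain) at the morphotype transition (accrual rises with shear)."""
    if p.carpet_shear_gain <= 0 or p.tau_end_pa <= p.tau_star_pa:
        return np.ones_like(tau)
    rise = np.clip(tau - p.tau_star_pa, 0.0, None) / (p.tau_end_pa - p.tau_star_pa)
    return (1.0 + p.carpet_shear_gain * rise) / (1.0 + p.carpet_shear_gain)


def _masked_carpet(p: LandscapeParams, rng: np.random.Generator,
                   shape: tuple[int, int]) -> np.ndarray:
    """FFM carpet: smoothed thresholded random field, normalized so the mean
    thickness over covered pixels equals ``carpet_mean_mm``."""
    if p.carpet_mean_mm <= 0 or p.carpet_coverage <= 0:
        return np.zeros(shape)
    s = _grf(shape, p.carpet_corr_mm / p.pixel_size_mm, rng)
    thr = np.quantile(s, 1.0 - p.carpet_coverage)
    excess = np.maximum(s - thr, 0.0)
    covered = excess > 0
    if not covered.any():
        return np.zeros(shape)
    return p.carpet_mean_mm * excess / excess[covered].mean()


def _floor_mask(p: LandscapeParams, rng: np.random.Generator,
                shape: tuple[int, int]) -> np.ndarray:
    if p.floor_height_mm <= 0 or p.floor_coverage <= 0:
        return np.zeros(shape)
    s = _grf(shape, p.floor_corr_mm / p.pixel_size_mm, rng)
    thr = np.quantile(s, 1.0 - p.floor_coverage)
    return np.where(s > thr, p.floor_height_mm, 0.0)


def _colonies(p: LandscapeParams, rng: np.random.Generator,
              shape: tuple[int, int], sfm_w: np.ndarray) -> np.ndarray:
    """Small (<100 um) trough colonies on the SFM side."""
    ny, nx = shape
    px = p.pixel_size_mm
    out = np.zeros(shape)
    n = rng.poisson(p.colony_density_mm2 * ny * nx * px ** 2)
    if n == 0 or p.colony_amp_mm[1] <= 0:
        return out
    rows = rng.uniform(0, ny, n)
    cols = rng.uniform(0, nx, n)
    keep = rng.random(n) < sfm_w[cols.astype(int)]
    amps = rng.uniform(*p.colony_amp_mm, n)
    sigs = rng.uniform(*p.colony_sigma_mm, n) / px
    for i in np.flatnonzero(keep):
        gaussian_bump_field(shape, rows[i], cols[i], sigs[i], sigs[i],
                            amps[i], out=out)
    return out


def measurement_model(field: np.ndarray, p: LandscapeParams,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply OCT artefacts: optional sensor noise, depth clip, z-quantization."""
    h = field
    if p.noise_sigma_mm > 0:
        if rng is None:
            raise ValidationError("noise requested but no RNG supplied")
        h = h + rng.normal(0.0, p.noise_sigma_mm, h.shape)
    h = np.clip(h, 0.0, p.clip_mm)
    return np.round(h / p.z_quantum_mm) * p.z_quantum_mm


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_landscape(params: LandscapeParams | None = None, seed: int = 0,
                  day: int = 15, flume_id: str = "I",
                  ) -> tuple[DEMGrid, GroundTruth]:
    """One-day synthetic landscape along the shear gradient."""
    p = params or LandscapeParams()
    shape = p.shape()
    rng = np.random.default_rng(seed)

    clusters = _place_clusters(p, rng, shape)
    carpet = _masked_carpet(p, rng, shape)
    floor = _floor_mask(p, rng, shape)
    tau = _tau_per_column(p, shape[1])
    w = ffm_weight(tau, p.tau_star_pa, p.logistic_width_pa)
    colonies = _colonies(p, rng, shape, 1.0 - w)

    field = (carpet * (w * _carpet_gain(p, tau))[None, :]
             + (floor + colonies) * (1.0 - w[None, :]))
    for _, c in clusters.iterrows():
        gaussian_bump_field(shape, c["row"], c["col"],
                            c["sigma_y_mm"] / p.pixel_size_mm,
                            c["sigma_x_mm"] / p.pixel_size_mm,
                            c["amp_mm"], out=field)

    heights = measurement_model(field, p, rng)
    grid = DEMGrid(heights=heights, pixel_size_mm=p.pixel_size_mm,
                   z_quantum_mm=p.z_quantum_mm, day=day, flume_id=flume_id,
                   clip_mm=p.clip_mm)
    truth = GroundTruth(clusters=clusters, noiseless=field,
                        params=asdict(p), seed=seed)
    return grid, truth


def gen_timeseries(params: LandscapeParams | None = None, seed: int = 0,
                   days: tuple[int, ...] = (0, 3, 6, 9, 12, 15),
                   growth_rate: float = np.log(2) / 3.0,
                   detach_prob: float = 0.05,
                   displace_prob: float = 0.3,
                   shift_px: int = 75,
                   flume_id: str = "I",
                   ) -> tuple[DEMSeries, GroundTruth]:
    """Growth series with detachment and downstream-displacement events.

    Heights grow exponentially at ``growth_rate`` per day (default: doubling
    every 3 days), referenced so the final day matches the single-landscape
    draw. In each interval, every SFM cluster independently detaches with
    ``detach_prob`` or is pushed ``shift_px`` pixels downstream with
    ``displace_prob``; the carpet grows without events. All events are
    logged with the analytic cluster volume at the event day.
    """
    p = params or LandscapeParams()
    if len(days) < 2 or any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ValidationError("days must be strictly increasing, >=2 entries")
    shape = p.shape()
    rng = np.random.default_rng(seed)

    clusters = _place_clusters(p, rng, shape)
    carpet = _masked_carpet(p, rng, shape)
    floor = _floor_mask(p, rng, shape)
    tau = _tau_per_column(p, shape[1])
    w = ffm_weight(tau, p.tau_star_pa, p.logistic_width_pa)
    colonies = _colonies(p, rng, shape, 1.0 - w)
    ref_day = days[-1]

    n_cl = len(clusters)
    detached_day = np.full(n_cl, np.iinfo(np.int64).max)
    cum_shift = np.zeros(n_cl)
    events: list[dict] = []
    grids: list[DEMGrid] = []
    noiseless_by_day: dict[int, np.ndarray] = {}

    for k, d in enumerate(days):
        if k > 0:
            # events happening during the interval ending at day d
            for i in range(n_cl):
                if detached_day[i] <= d:
                    continue
                u = rng.random()
                scale_d = np.exp(growth_rate * (d - ref_day))
                vol = float(clusters.at[i, "volume_mm3"]) * min(
                    scale_d, p.amp_cap_mm / clusters.at[i, "amp_mm"])
                if u < detach_prob:
                    detached_day[i] = d
                    events.append({"day": int(d), "cluster_id": int(i),
                                   "event": "detach", "volume_mm3": vol})
                elif u < detach_prob + displace_prob:
                    cum_shift[i] += shift_px
                    events.append({"day": int(d), "cluster_id": int(i),
                                   "event": "displace", "shift_px": int(shift_px),
                                   "volume_mm3": vol})
        scale = np.exp(growth_rate * (d - ref_day))
        field = (carpet * (w * _carpet_gain(p, tau))[None, :]
                 + (floor + colonies) * (1 - w[None, :])) * scale
        for i, c in clusters.iterrows():
            if detached_day[i] <= d:
                continue
            gaussian_bump_field(shape, c["row"], c["col"] + cum_shift[i],
                                c["sigma_y_mm"] / p.pixel_size_mm,
                                c["sigma_x_mm"] / p.pixel_size_mm,
                                min(c["amp_mm"] * scale, p.amp_cap_mm),
                                out=field)
        noiseless_by_day[int(d)] = field
        grids.append(DEMGrid(heights=measurement_model(field, p, rng),
                             pixel_size_mm=p.pixel_size_mm,
                             z_quantum_mm=p.z_quantum_mm, day=int(d),
                             flume_id=flume_id, clip_mm=p.clip_mm))

    truth = GroundTruth(clusters=clusters, events=events,
                        noiseless=noiseless_by_day[int(ref_day)],
                        noiseless_by_day=noiseless_by_day,
                        params=asdict(p), seed=seed)
    return DEMSeries(grids=grids), truth


def gen_hydraulic_profile(params: LandscapeParams | None = None,
                          n_rows: int = 41,
                          u_range: tuple[float, float] = (0.06, 0.13),
                          re_range: tuple[float, float] = (793.0, 1407.0),
                          ) -> HydraulicProfile:
    """Linear streamwise hydraulic table spanning the study's ranges
    (U 0.06->0.13 m/s, tau 0.04->0.13 Pa, Re 793->1407)."""
    p = params or LandscapeParams()
    x = np.linspace(0.0, p.extent_m[1], n_rows)
    t = x / p.extent_m[1]
    return HydraulicProfile(pd.DataFrame({
        "x_m": x,
        "U_m_s": u_range[0] + (u_range[1] - u_range[0]) * t,
        "tau_Pa": p.tau_start_pa + (p.tau_end_pa - p.tau_start_pa) * t,
        "Re": re_range[0] + (re_range[1] - re_range[0]) * t,
    }))


# ---------------------------------------------------------------------------
# oxygen
# ---------------------------------------------------------------------------

def closed_form_oxygen(z, c0: float, kd: float, L: float, mode: str = "dark",
                       dbl_mm: float = 0.0) -> np.ndarray:
    """Steady-state zero-order diffusion–reaction profile.

    Dark: C(z) = C0 - (R/D)(Lz - z^2/2) for 0 <= z <= L (consumption R,
    surface held at C0, no-flux base). Light: same with net production,
    C(z) = C0 + (P/D)(Lz - z^2/2). Above the surface the concentration is
    the bulk value, with an optional linear diffusive boundary layer of
    thickness ``dbl_mm`` matching the surface flux.
    """
    z = np.asarray(z, dtype=float)
    sign = 1.0 if mode == "dark" else -1.0
    zi = np.clip(z, 0.0, L)
    c = c0 - sign * kd * (L * zi - zi ** 2 / 2.0)
    if dbl_mm > 0:
        # linear layer continuous with the interior surface gradient -R/D*L
        above = (z < 0) & (z >= -dbl_mm)
        c = np.where(above, c0 + sign * kd * L * z, c)
        c = np.where(z < -dbl_mm, c0 + sign * kd * L * (-dbl_mm), c)
    else:
        c = np.where(z < 0, c0, c)
    return c


def gen_oxygen(params: OxygenParams | None = None, seed: int = 0,
               ) -> tuple[OxygenProfileSet, GroundTruth]:
    """Synthetic oxygen microprofile set for both morphotypes.

    Per profile, a lognormal multiplier on the consumption/production rate
    (wider for the SFM, matching its stronger structural heterogeneity)
    plus Gaussian sensor noise. A separate SFM dark transect varies the
    distance to the nearest cluster wall, with consumption relieved by
    ``wall_delta * exp(-distance/wall_lambda)`` to emulate advective
    replenishment through the cluster side walls. Negative closed-form
    values are truncated at 0 with a warning and a truth flag.
    """
    p = params or OxygenParams()
    if p.sfm_L_mm <= 0 or p.ffm_L_mm <= 0:
        raise ValidationError("biofilm thickness L must be positive")
    rng = np.random.default_rng(seed)
    profiles: list[OxygenProfile] = []
    truncated = False

    def build(pid, morph, cond, kd, L, wall=None):
        nonlocal truncated
        z = np.arange(-p.z_above_mm, L + p.dz_mm / 2, p.dz_mm)
        c = closed_form_oxygen(z, p.c0, kd, L, mode=cond, dbl_mm=p.dbl_mm)
        if np.any(c < 0):
            truncated = True
            warnings.warn(f"profile {pid}: closed form went negative, truncated",
                          stacklevel=2)
            c = np.maximum(c, 0.0)
        if p.noise_umol > 0:
            c = np.maximum(c + rng.normal(0, p.noise_umol, c.shape), 0.0)
        profiles.append(OxygenProfile(depths=z, concentrations=c,
                                      condition=cond, morphotype=morph,
                                      profile_id=pid, wall_distance_mm=wall))

    for morph, n, rd, pdp, L, spread in (
            ("SFM", p.sfm_n, p.sfm_rd, p.sfm_pd, p.sfm_L_mm, p.sfm_spread),
            ("FFM", p.ffm_n, p.ffm_rd, p.ffm_pd, p.ffm_L_mm, p.ffm_spread)):
        for i in range(n):
            m = rng.lognormal(0.0, spread)
            pid = f"{morph}-{i:02d}"
            build(pid, morph, "dark", rd * m, L)
            build(pid, morph, "light", pdp * m, L)

    for wdist in p.wall_distances_mm:
        relief = 1.0 - p.wall_delta * np.exp(-wdist / p.wall_lambda_mm)
        for r in range(p.wall_reps):
            m = rng.lognormal(0.0, p.sfm_spread / 2)
            build(f"SFM-wall-{wdist:g}-{r}", "SFM", "dark",
                  p.sfm_rd * relief * m, p.sfm_L_mm, wall=wdist)

    truth = GroundTruth(params=asdict(p), seed=seed,
                        oxygen={"truncated": truncated,
                                "sfm_dark_base": float(closed_form_oxygen(
                                    p.sfm_L_mm, p.c0, p.sfm_rd, p.sfm_L_mm)),
                                "ffm_dark_base": float(closed_form_oxygen(
                                    p.ffm_L_mm, p.c0, p.ffm_rd, p.ffm_L_mm))})
    return OxygenProfileSet(profiles), truth
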