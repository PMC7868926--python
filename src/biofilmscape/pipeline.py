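"""End-to-end pipeline stages over a run directory.

Each stage reads its inputs from the run directory (or from external paths
named in the config), writes its outputs there, and logs provenance
(config hash, seed, package version). Stages: simulate -> metrics ->
segment -> dynamics -> breakpoint -> oxygen -> report. All randomness is
funneled through seeds derived from the single configured seed, so a rerun
with the same config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dem_io import DEMGrid, load_series, write_series
from .exceptions import FitError, ValidationError
from .hydraulics import HydraulicProfile
from .landscape_metrics import moving_window_metrics
from .segmentation import extract_clusters, segment_landscape
from .temporal_dynamics import series_differences
from .breakpoint_stats import (BreakpointFit, breakpoint_significance,
                               fit_segmented, replicate_consensus)
from .oxygen_profiles import (OxygenProfileSet, brown_forsythe_test,
                              grouped_depth_compare, light_dark_ratio,
                              parse_profiles, welch_test)
from .synthetic_data import (LandscapeParams, OxygenParams, gen_hydraulic_profile,
                             gen_oxygen, gen_timeseries)

log = logging.getLogger("biofilmscape")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "flumes": ["I", "II"],
    "landscape": {},  # overrides for LandscapeParams fields
    "timeseries": {"days": [0, 3, 6, 9, 12, 15], "detach_prob": 0.05,
                   "displace_prob": 0.3, "shift_px": 75},
    "oxygen_params": {},  # overrides for OxygenParams fields
    "metrics": {"window_mm": 24.0, "step_mm": 2.0, "h_min": 0.010},
    "segmentation": {"local_window_mm": 24.0, "k_hi": 2.0, "k_lo": 2.0,
                     "h_min": 0.010, "min_area_mm2": 0.01},
    "dynamics": {"denominator": "later"},
    "breakpoint": {"n_boot": 199, "alpha": 0.05,
                   "metrics": ["volume_mm3", "coverage", "porosity",
                               "mean_thickness_mm", "textural_correlation",
                               "accrual_rate_mm3_day"]},
    "paths": {"manifests": None, "hydraulics": None, "oxygen": None},
}

STAGES = ("simulate", "metrics", "segment", "dynamics", "breakpoint",
          "oxygen", "report")


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None,
                ) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        cfg = _deep_merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder,
                               allow_nan=True))


def setup_run(cfg: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("biofilmscape %s run: config_hash=%s seed=%s",
             __version__, _config_hash(cfg), cfg.get("seed"))
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir


def _params_from_cfg(cls, overrides: dict):
    names = {f.name for f in dc_fields(cls)}
    bad = set(overrides) - names
    if bad:
        raise ValidationError(f"unknown {cls.__name__} fields: {sorted(bad)}")
    kw = {k: (tuple(v) if isinstance(v, list) else v)
          for k, v in overrides.items()}
    return cls(**kw)


def _flume_seed(cfg: dict, idx: int) -> int:
    return (int(cfg["seed"]) * 1000 + idx) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: dict, outdir: Path) -> None:
    lp = _params_from_cfg(LandscapeParams, cfg["landscape"])
    ts = cfg["timeseries"]
    for i, fid in enumerate(cfg["flumes"]):
        series, truth = gen_timeseries(
            lp, seed=_flume_seed(cfg, i), days=tuple(ts["days"]),
            detach_prob=ts["detach_prob"], displace_prob=ts["displace_prob"],
            shift_px=ts["shift_px"], flume_id=str(fid),
            **({"growth_rate": ts["growth_rate"]} if "growth_rate" in ts else {}))
        ddir = outdir / "dems" / f"flume{fid}"
        write_series(series, ddir)
        truth.clusters.to_csv(ddir / "truth_clusters.csv", index=False)
        _dump_json({"events": truth.events, "seed": truth.seed},
                   ddir / "truth_events.json")
        log.info("simulate: flume %s, %d days, %d clusters, %d events",
                 fid, len(series), len(truth.clusters), len(truth.events))
    gen_hydraulic_profile(lp).to_csv(outdir / "hydraulics.csv")
    op = _params_from_cfg(OxygenParams, cfg["oxygen_params"])
    pset, otruth = gen_oxygen(op, seed=_flume_seed(cfg, 99))
    pset.write_csv(outdir / "oxygen.csv")
    _dump_json(otruth.oxygen, outdir / "truth_oxygen.json")
    log.info("simulate: %d oxygen profiles", len(pset))


def _series_for(cfg: dict, outdir: Path, fid: str):
    override = cfg["paths"].get("manifests")
    if override:
        return load_series(override[str(fid)])
    return load_series(outdir / "dems" / f"flume{fid}" / "manifest.csv")


def _profile_for(cfg: dict, outdir: Path) -> HydraulicProfile:
    path = cfg["paths"].get("hydraulics") or outdir / "hydraulics.csv"
    return HydraulicProfile.from_csv(path)


def run_metrics(cfg: dict, outdir: Path) -> None:
    profile = _profile_for(cfg, outdir)
    m = cfg["metrics"]
    for fid in cfg["flumes"]:
        series = _series_for(cfg, outdir, fid)
        last = series.grids[-1]
        earlier = series.grids[-2] if len(series) >= 2 else None
        table = moving_window_metrics(
            last, profile, window_mm=m["window_mm"], step_mm=m["step_mm"],
            h_min=m["h_min"], earlier=earlier)
        table.to_csv(outdir / f"window_metrics_flume{fid}.csv", index=False)
        log.info("metrics: flume %s day %d, %d windows", fid, last.day, len(table))


def _end_regions(grid: DEMGrid) -> dict[str, tuple]:
    """Low-shear (SFM) and high-shear (FFM) quarters of the strip."""
    q = grid.n_cols // 4
    return {"SFM": (0, grid.n_rows, 0, q),
            "FFM": (0, grid.n_rows, grid.n_cols - q, grid.n_cols)}


def run_segment(cfg: dict, outdir: Path) -> None:
    s = cfg["segmentation"]
    for fid in cfg["flumes"]:
        series = _series_for(cfg, outdir, fid)
        grid = series.grids[-1]
        segmap, fractions = segment_landscape(
            grid, local_window_mm=s["local_window_mm"], k_hi=s["k_hi"],
            k_lo=s["k_lo"], h_min=s["h_min"])
        stats, labeled = extract_clusters(segmap, grid, s["min_area_mm2"])
        tifffile.imwrite(outdir / f"labels_flume{fid}.tif", segmap.labels)
        stats.to_csv(outdir / f"clusters_flume{fid}.csv", index=False)

        out = {"whole": fractions}
        for name, (r0, r1, c0, c1) in _end_regions(grid).items():
            sub = segmap.labels[r0:r1, c0:c1]
            n = sub.size
            out[name] = {
                "f_bare": float((sub == 0).sum()) / n,
                "f_trough": float((sub == 1).sum()) / n,
                "f_base": float((sub == 2).sum()) / n,
                "f_cluster": float((sub == 3).sum()) / n,
            }
            out[name]["f_trough_incl_bare"] = out[name]["f_trough"] + out[name]["f_bare"]
        _dump_json(out, outdir / f"fractions_flume{fid}.json")
        log.info("segment: flume %s, %d clusters retained", fid, len(stats))


def run_dynamics(cfg: dict, outdir: Path) -> None:
    d = cfg["dynamics"]
    for fid in cfg["flumes"]:
        series = _series_for(cfg, outdir, fid)
        diffs = series_differences(series, denominator=d["denominator"])
        rows = []
        for dm in diffs:
            tifffile.imwrite(
                outdir / f"delta_flume{fid}_d{dm.day_pair[0]}_d{dm.day_pair[1]}.tif",
                dm.delta.astype(np.float32))
            rows.append({"day_start": dm.day_pair[0], "day_end": dm.day_pair[1],
                         "positive_volume_mm3": dm.positive_volume,
                         "negative_volume_mm3": dm.negative_volume,
                         "displaced_fraction": dm.displaced_fraction})
        pd.DataFrame(rows).to_csv(outdir / f"dynamics_flume{fid}.csv", index=False)
        log.info("dynamics: flume %s, %d day pairs", fid, len(rows))


def run_breakpoint(cfg: dict, outdir: Path) -> None:
    b = cfg["breakpoint"]
    m = cfg["metrics"]
    thin = max(1, int(round(m["window_mm"] / m["step_mm"])))
    results: dict[str, dict] = {}
    for metric in b["metrics"]:
        per_flume = {}
        fits: list[BreakpointFit] = []
        for fid in cfg["flumes"]:
            path = outdir / f"window_metrics_flume{fid}.csv"
            if not path.is_file():
                raise FitError(f"missing {path}; run the metrics stage first")
            table = pd.read_csv(path)
            if metric not in table.columns:
                continue
            x = table["tau_Pa"].to_numpy()
            y = table[metric].to_numpy()
            try:
                fit = fit_segmented(x, y)
                # inference on spatially thinned windows (non-overlapping)
                xt, yt = x[::thin], y[::thin]
                try:
                    fit.p_value = breakpoint_significance(
                        xt, yt, n_boot=b["n_boot"],
                        seed=_flume_seed(cfg, 7) + zlib.crc32(metric.encode()) % 10000)
                except FitError as exc:
                    log.warning("breakpoint: %s flume %s: thinned inference "
                                "failed (%s)", metric, fid, exc)
                fits.append(fit)
                per_flume[str(fid)] = vars(fit).copy()
            except FitError as exc:
                log.warning("breakpoint: %s flume %s: %s", metric, fid, exc)
        if per_flume:
            consensus = None
            if len(fits) >= 2 and all(f.p_value is not None for f in fits):
                consensus = replicate_consensus(fits, alpha=b["alpha"])
            results[metric] = {"per_flume": per_flume, "consensus": consensus}
    _dump_json(results, outdir / "breakpoints.json")
    log.info("breakpoint: %d metrics analysed", len(results))


def run_oxygen(cfg: dict, outdir: Path) -> None:
    path = cfg["paths"].get("oxygen") or outdir / "oxygen.csv"
    pset = parse_profiles(path)
    res: dict = {}

    def values(morph, cond):
        sub = pset.select(condition=cond, morphotype=morph)
        sub = OxygenProfileSet([p for p in sub if p.wall_distance_mm is None])
        return np.concatenate([p.concentrations[p.depths >= 0] for p in sub]) \
            if len(sub) else np.array([])

    for cond in ("dark", "light"):
        a, b = values("SFM", cond), values("FFM", cond)
        if len(a) > 1 and len(b) > 1:
            w, p = brown_forsythe_test(a, b)
            res[f"brown_forsythe_{cond}"] = {"W": w, "p": p,
                                             "var_SFM": float(a.var(ddof=1)),
                                             "var_FFM": float(b.var(ddof=1))}
            res[f"min_{cond}"] = {"SFM": float(a.min()), "FFM": float(b.min())}

    ratios: dict[str, list[float]] = {"SFM": [], "FFM": []}
    by_id: dict[str, dict] = {}
    for p in pset:
        if p.wall_distance_mm is None:
            by_id.setdefault(p.profile_id, {})[p.condition] = p
    for pid, pair in sorted(by_id.items()):
        if {"light", "dark"} <= set(pair):
            try:
                r = light_dark_ratio(pair["light"], pair["dark"])
            except ValidationError:
                continue
            if np.isfinite(r):
                ratios[pair["dark"].morphotype].append(r)
    if all(len(v) >= 2 for v in ratios.values()):
        t, df, pv = welch_test(ratios["SFM"], ratios["FFM"])
        res["light_dark_ratio"] = {
            "mean_SFM": float(np.mean(ratios["SFM"])),
            "mean_FFM": float(np.mean(ratios["FFM"])),
            "welch_t": t, "welch_df": df, "welch_p": pv}

    depth_cmp = grouped_depth_compare(
        pset.select(morphotype="SFM", condition="dark"),
        pset.select(morphotype="FFM", condition="dark"), bin_mm=0.1)
    depth_cmp.to_csv(outdir / "oxygen_depth_compare.csv", index=False)

    wall = pset.select(condition="dark", wall_max_mm=0.2)
    core = pset.select(condition="dark", wall_min_mm=0.8)
    if len(wall) and len(core):
        wall_cmp = grouped_depth_compare(wall, core, bin_mm=0.1)
        wall_cmp.to_csv(outdir / "oxygen_wall_compare.csv", index=False)
        res["wall_vs_core_bins_q_lt_0.01"] = int(
            ((wall_cmp["q"] < 0.01) & (wall_cmp["note"] == "ok")).sum())
    _dump_json(res, outdir / "oxygen_stats.json")
    log.info("oxygen: %d profiles analysed", len(pset))


def run_report(cfg: dict, outdir: Path) -> None:
    summary: dict = {"config_hash": _config_hash(cfg), "seed": cfg["seed"],
                     "version": __version__}
    for name in ("breakpoints", "oxygen_stats"):
        f = outdir / f"{name}.json"
        if f.is_file():
            summary[name] = json.loads(f.read_text())
    for fid in cfg["flumes"]:
        f = outdir / f"fractions_flume{fid}.json"
        if f.is_file():
            summary[f"fractions_flume{fid}"] = json.loads(f.read_text())
        f = outdir / f"dynamics_flume{fid}.csv"
        if f.is_file():
            summary[f"dynamics_flume{fid}"] = pd.read_csv(f).to_dict("records")
    _dump_json(summary, outdir / "summary.json")

    try:  # quick-look figure of the windowed metrics against shear
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
        cols = ["volume_mm3", "accrual_rate_mm3_day", "mean_thickness_mm",
                "coverage", "porosity", "textural_correlation"]
        for fid in cfg["flumes"]:
            f = outdir / f"window_metrics_flume{fid}.csv"
            if not f.is_file():
                continue
            t = pd.read_csv(f)
            for ax, col in zip(axes.ravel(), cols):
                if col in t:
                    ax.plot(t["tau_Pa"], t[col], label=f"flume {fid}")
                ax.set_title(col)
        for ax in axes[-1]:
            ax.set_xlabel("bed shear stress (Pa)")
        axes[0, 0].legend()
        fig.tight_layout()
        fig.savefig(outdir / "report.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never fail the pipeline
        log.warning("report figure skipped: %s", exc)
    log.info("report: summary written")


_STAGE_FUNCS = {"simulate": run_simulate, "metrics": run_metrics,
                "segment": run_segment, "dynamics": run_dynamics,
                "breakpoint": run_breakpoint, "oxygen": run_oxygen,
                "report": run_report}


def run_pipeline(cfg: dict, outdir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in canonical order; halt on stage failure."""
    outdir = setup_run(cfg, outdir)
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception:
            log.exception("stage %s: FAILED", stage)
            raise
        log.info("stage %s: done", stage)
    return outdir
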