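# biofilmscape

Landscape morphometrics for phototrophic biofilms imaged along a hydraulic
gradient.

Benthic biofilms growing in flowing water differentiate into contrasting
architectures: under low bed shear stress they form tall clusters (up to
~1.5 mm) separated by troughs dotted with small (<100 µm) colonies — the
slow-flow morphotype (SFM) — while under high shear they grow as a thin,
coalescent carpet densely covering the substrate (fast-flow morphotype,
FFM). Optical coherence tomography (OCT) captures this as a digital
elevation model (DEM): a raster whose pixel gray level encodes local
biofilm thickness (40 µm lateral pixels, 2.18 µm height quantum).

`biofilmscape` provides the quantitative toolchain for such data, for
microbial ecologists and biofilm physicists working with surface-topography
rasters:

- **dem_io** — read/write DEMs (16-bit TIFF in quantum units, or plain-text
  mm grids) with YAML metadata sidecars; day-ordered series via a manifest
  CSV; depth-clipping diagnostics for the ~1.2 mm OCT imaging ceiling.
- **hydraulics** — tabulated streamwise profiles of mean velocity, bed
  shear stress τ and Reynolds number (interpolated, never extrapolated),
  plus analytic open-channel helpers (Re = U·R_h/ν, plane-laminar
  τ = 3µU/h).
- **landscape_metrics** — per-region and moving-window (24 mm edge)
  biovolume ∑h·Δx², coverage, thickness statistics, envelope porosity
  1 − V/(A·h₉₉), and Haralick textural correlation of the gray-level
  co-occurrence matrix (a proxy for biomass aggregation).
- **segmentation** — classification by deviation from the local average
  thickness m: cluster (h ≥ 2m), trough (h ≤ m/2), base biofilm, and bare
  substrate (h below the detection threshold); 8-connected cluster objects
  with volume, aspect ratios and size distributions.
- **temporal_dynamics** — subtraction of subsequent DEMs: accrual rates and
  the signed volume budget, where "negative growth" pixels quantify biomass
  detached or displaced in the flow direction
  (positive_volume − negative_volume ≡ ΔV, exactly).
- **breakpoint_stats** — segmented regression
  y = β₀ + β₁τ + β₂(τ − ψ)₊ of each metric against shear, with ψ found by
  exhaustive candidate search, a residual-bootstrap F test against the
  straight-line null, and a both-replicates consensus rule.
- **oxygen_profiles** — microsensor profile parsing, local gradients over
  the 0.05–0.15 mm depth window, light:dark gradient ratios, Brown–Forsythe
  variance-heterogeneity tests, Welch t tests, and depth-binned (100 µm)
  comparisons with Benjamini–Hochberg correction.
- **synthetic_data** — a fully ground-truthed generator of SFM/FFM
  landscapes, growth series with detachment/displacement events, hydraulic
  tables, and closed-form diffusion–reaction oxygen profiles
  C(z) = C₀ ∓ (R/D)(Lz − z²/2); the test oracle for everything above.

## Worked example

```python
from biofilmscape import (LandscapeParams, gen_landscape, gen_hydraulic_profile,
                          moving_window_metrics, fit_segmented,
                          breakpoint_significance, segment_landscape,
                          extract_clusters)

params = LandscapeParams()                      # the default full-scale scene
grid, truth = gen_landscape(params, seed=1)     # 625 x 10000 px DEM, day 15
profile = gen_hydraulic_profile(params)         # tau: 0.04 -> 0.13 Pa

table = moving_window_metrics(grid, profile)    # 24 mm windows, 2 mm stride
fit = fit_segmented(table["tau_Pa"], table["volume_mm3"])
p = breakpoint_significance(table["tau_Pa"][::12], table["volume_mm3"][::12],
                            n_boot=199, seed=1)
print(f"volume breakpoint: {fit.psi:.3f} Pa "
      f"(slopes {fit.slope_below:.0f} -> {fit.slope_above:.0f} mm^3/Pa, p = {p:.3f})")

segmap, fractions = segment_landscape(grid)
clusters, _ = extract_clusters(segmap, grid)
print(f"cluster cover: {fractions['f_cluster']:.1%}, "
      f"troughs incl. bare: {fractions['f_trough_incl_bare']:.1%}")
```

prints

```
volume breakpoint: 0.071 Pa (slopes 16 -> 1679 mm^3/Pa, p = 0.020)
cluster cover: 6.2%, troughs incl. bare: 43.0%
```

Biofilm volume is essentially flat with shear below the breakpoint and
rises steeply above it (slopes 16 vs 1679 mm³/Pa); the bootstrap test
rejects the straight-line null at p = 0.02. Over the whole strip the
protruding clusters cover ~6% of the substrate while troughs and bare
substrate make up ~43% (the low-shear half alone is trough-dominated).

## Command line

Each analysis stage is independently runnable over a run directory:

```sh
biofilmscape all --out runs/demo --seed 1          # simulate -> ... -> report
biofilmscape simulate --config my.yaml --out runs/x
```

Stages: `simulate`, `metrics`, `segment`, `dynamics`, `breakpoint`,
`oxygen`, `report`. Outputs are CSV/JSON tables, 8-bit label and float32
difference TIFFs, a provenance log, and a summary figure.

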