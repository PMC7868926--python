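# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `biofilmscape`. Everything quantitative claimed here is
computed by the test suite or by `scripts/acceptance.py`; nothing is taken
on faith from external data.

## DEM representation and measurement model

A biofilm surface DEM is a 2D raster of thickness values in mm. Rows run
cross-flume, columns run streamwise with x increasing in the flow
direction; pixel centers sit at `(i + 0.5) * pixel_size`. Defaults follow
the OCT acquisition this package targets: 40 µm lateral pixels and a
2.18 µm height quantum. On disk, TIFF DEMs hold 16-bit gray levels in
quantum units (so a write/read round trip is lossy only below half a
quantum); text grids hold mm at full float precision. OCT does not reliably
image structures taller than ~1.2 mm, so heights at the configurable device
ceiling are flagged in a clipping mask and summarized as a
clipped-fraction diagnostic — they remain valid (censored) heights rather
than being removed, which means volumes and thickness statistics are lower
bounds wherever the clipped fraction is non-zero.

## Landscape metrics

All metrics operate on half-open pixel rectangles; the moving-window
variant uses a square window (default 24 mm edge, 2 mm stride) taken from a
centered cross-flume band when the strip is wider than the window edge
(the 25 mm strip vs the 24 mm window). Definitions:

- biovolume: Σ h · pixel_area (mm³).
- coverage: fraction of pixels with h ≥ h_min. The detection threshold
  h_min defaults to 0.010 mm ≈ 5 height quanta — above quantization noise,
  well below the <100 µm colonies it must retain. No instrument-stated
  threshold exists; this is a package choice.
- thickness statistics (mean over covered pixels, max, 99th percentile).
- porosity: 1 − V/(A · h₉₉), the void fraction of the envelope box bounded
  by the 99th-percentile height, clipped to [0, 1]; an uncovered region is
  all void (porosity 1) by convention. This is a surface-DEM surrogate for
  porosity definitions that operate on full 3D biomass grids; it is
  isolated behind one function so an alternative definition can be swapped
  in.
- textural correlation: the Haralick correlation of the gray-level
  co-occurrence matrix. Heights are quantized to 64 levels over
  [0, window max]; symmetric, normalized co-occurrence matrices are built
  for the four unit-distance offsets (E, S, SE, NE) and the correlation is
  averaged over offsets. Constant windows return NaN (the variance
  normalizer vanishes) and are excluded from downstream regression. The
  co-occurrence counting is implemented in-module (bincount over paired
  level codes) because arbitrary signed offsets and per-window quantization
  bounds are needed; it is verified against a brute-force pair-enumeration
  oracle to 1e-10 and against `skimage.feature.graycomatrix` for the
  shared offset.

## Segmentation

Pixels are classified by deviation from the local average thickness m:
bare (h < h_min), cluster (h ≥ 2m), trough (h ≤ m/2), else base biofilm.
The 2× factors are symmetric by construction ("two times larger/lower than
the local average"); both are configurable. The local mean is an
edge-clipped box average (mean over the window∩grid intersection) computed
by integral image, including zero-height pixels — it is the local average
of the landscape, not of the covered area (a covered-only variant would
inflate m inside troughs). The local window defaults to the same 24 mm as
the moving-window analysis, the only landscape length scale in play.

Bare substrate is kept separate from troughs so that trough fractions are
not inflated by uncolonized plexiglass; because reporting conventions for
trough cover often merge the two, the merged trough+bare fraction is
always reported alongside. Cluster objects are
8-connected components of cluster-class pixels; components below 0.01 mm²
(~6 pixels) are discarded as speckle. Per-cluster morphology includes
volume, bounding extents along/across flow, the vertical aspect
(max height / equivalent diameter) and horizontal aspect
(flow length / cross width).

## Temporal dynamics

Subtracting subsequent DEMs gives a signed height-change map; positive and
negative volumes are integrated separately and obey
positive − negative = ΔV exactly. Negative deltas strictly smaller than one
height quantum are zeroed before integration to suppress quantization
flicker (the cutoff is backed off by a relative epsilon so a genuine
one-quantum drop, stored with float rounding, survives); quantized DEMs
are unaffected, keeping the conservation identity exact. The displaced
fraction divides negative volume by the later-day biovolume by default
(earlier/mean are options; the reference day is genuinely ambiguous).
Grids are assumed co-registered — the automated OCT stage re-scans fixed
positions — and no registration is applied by default, because aligning
away bulk motion would erase precisely the displacement signal being
measured; an optional integer-shift cross-correlation pre-alignment exists
for data that need it.

## Breakpoint regression

Each windowed metric y is regressed on bed shear stress τ with the
continuous broken-line model y = β₀ + β₁τ + β₂(τ − ψ)₊ + ε. ψ is estimated
by exhaustive search over the observed interior τ values within the
5th–95th percentile range (deterministic and directly checkable against a
brute-force fit, unlike iterative refitting, which remains available
through the same RSS machinery); the RSS minimizer wins, with batched QR
factorizations making the search and its bootstraps cheap. When the
segmented model does not improve on the straight line the fit is flagged
unidentified. Significance uses a residual bootstrap under the linear
null: resample linear-fit residuals, refit both models, and compare
F = ((RSS_lin − RSS_seg)/2)/(RSS_seg/(n − 4)) with its null distribution;
the Monte-Carlo p-value (1+k)/(1+B) is exact under the null, and the
type-I error is verified at 5% ± 2% by simulation. Because overlapping
windows are spatially autocorrelated, inference runs by default on windows
thinned to one stride per window edge, while ψ estimation uses all
windows. A consensus breakpoint range [min ψ̂, max ψ̂] is reported only when
the test rejects in every replicate flume.

## Oxygen microprofiles

Profiles are depth series of dissolved oxygen (µmol/L) with depth zero at
the biofilm surface. When no measured surface position is supplied, the
surface is estimated as the depth of steepest concentration change in dark
profiles (and the method logged). Local gradients are OLS slopes over the
0.05–0.15 mm depth window (robust to sensor noise; a two-point mode
exists). The light:dark gradient ratio |slope_light|/|slope_dark| proxies
net autotrophic vs heterotrophic aerial oxygen flux and is scale-invariant
in concentration. Variance heterogeneity between morphotypes uses the
Brown–Forsythe (median-centered Levene) test; location comparisons use
Welch's t with Satterthwaite degrees of freedom; both delegate to scipy
and are verified against hand-evaluated textbook formulas to 1e-10.
Depth-binned comparisons pool samples in 100 µm steps (point-level pooling
by default; profile-level pooling — one mean per profile per bin — is an
option because the right pooling unit is genuinely unclear), skip bins
with n < 2 on either side, and report Benjamini–Hochberg q-values across
bins alongside the raw p-values.

## Synthetic data generator

The generator is the package's ground truth and defines the conditions the
analysis is validated under. Its defaults emulate the flume experiment at full scale:
a 0.025 m × 0.4 m strip at 40 µm pixels with bed shear rising linearly
0.04 → 0.13 Pa, a logistic morphotype blend centered at τ* = 0.08 Pa with
0.005 Pa width (the morphological transition is abrupt), and acquisition
every 3 days to day 15.

- SFM side: anisotropic Gaussian caps (streamwise elongation 1.4×) placed
  by an inhomogeneous hardcore point process (nominal 0.03 mm⁻², 4 mm
  minimum separation, 3 mm edge margin), amplitude lognormal with median
  1.0 mm capped at 1.5 mm; a patchy 0.02 mm floor (45% cover) and small
  colonies (0.02–0.08 mm) fill the troughs. The Gaussian cap is chosen for
  testability: its analytic volume 2π·σx·σy·A anchors volume-recovery
  oracles. Ground truth records exactly what was placed, so hardcore
  rejections never desynchronize truth from scene.
- FFM side: a smoothed thresholded Gaussian random field carpet (92%
  cover, 2 mm correlation length, 0.25 mm outlet thickness) that thins
  toward the transition by a shear gain factor (2.5): biomass accrual
  keeps rising with shear above the threshold but not below, which is the
  response shape the breakpoint analysis exists to detect.
- Dynamics: heights grow exponentially (doubling every 3 days, referenced
  to the final day); per interval each SFM cluster independently detaches
  (p = 0.05) or is displaced 3 mm downstream (p = 0.3, about one cluster
  diameter); every event is logged with the analytic cluster volume.
  Displacement dominates detachment, and displaced biovolume reaches
  ~10% of the day-15 SFM biovolume — a conservative estimate of
  shear-driven transport, since partial deformation and migrating ripples
  are not modelled and exponential growth doubles the denominator between
  acquisitions.
- Measurement model: clip at the 1.2 mm ceiling, then quantize to 2.18 µm.
  Additive sensor noise is available but defaults to zero: the upstream
  OCT reconstruction averages B-scans so residual noise sits below the
  height quantum, leaving quantization as the dominant artefact.
- Oxygen: steady-state zero-order closed forms with C₀ = 300 µmol/L.
  SFM: L = 0.5 mm, R/D = 2080 µmol L⁻¹ mm⁻² (base concentration 40);
  FFM: L = 0.25 mm, R/D = 3904 (base 178); P = R so the light:dark
  gradient ratio is 1. Per-profile lognormal rate multipliers (sd 0.12
  SFM / 0.05 FFM — wider in the structurally heterogeneous morphotype,
  narrow enough that dark profiles generally stay oxic) plus 2 µmol/L
  sensor noise. A wall transect relieves dark consumption by
  0.5·exp(−d/0.3 mm) with distance d to the nearest cluster wall,
  emulating advective replenishment through trough side walls. The
  zero-order form cannot reproduce measured light-profile maxima
  (photosynthesis is depth-structured in reality); only gradient-based and
  dark-profile statistics should be read off the light profiles.

All randomness flows through a single seeded `numpy.random.default_rng`
(PCG64); equal seeds give bit-identical scenes across platforms.

### What passing tests do and do not show

The generator's scenes are smooth caps and random-field carpets with
piecewise-closed-form oxygen profiles. Recovery of planted counts, volumes
and breakpoints under these conditions validates the estimators'
correctness, not their robustness to real OCT pathologies: speckle,
surface-detection failures over dense canopies, internal voids (absent in
the target system but not generally), partially deformed or oozing
biomass, and migratory ripples. Displacement is modelled as rigid
translation of whole clusters; real displacement mixes erosion,
deformation and redeposition, so the displaced-biovolume statistic on real
data is an interpretation, not a measurement of transport.

## Numerical choices

- Local means by integral image (float64 cumulative sums): matches a naive
  loop to ~1e-10; class thresholds compare quantized heights against these
  means, so boundary flips are possible only within that float slack.
- Candidate breakpoints at observed x values: ψ̂ is exactly equivariant
  under affine re-scaling of x, and exact piecewise-linear data are
  recovered exactly when the knot is a design point.
- Degenerate inputs: constant GLCM windows → NaN; uncovered regions →
  porosity 1 and zeroed thickness statistics with a coverage flag; zero
  dark gradients → NaN light:dark ratio; all-equal deviations → W = 0,
  p = 1; zero-variance-equal-mean Welch → t = 0, p = 1.
- Sub-quantum flicker cutoff backed off by 1e-6 relative so one-quantum
  drops survive float representation.
- Bootstrap p-values use (1+k)/(1+B) with B = 199 by default (p-resolution
  0.005, exact validity); seeds are mandatory on every bootstrap path.

## Problem sizes

The test suite validates on reduced scenes (strips of a few cm, hundreds
of windows at most) with the full flume scale exercised by
`scripts/acceptance.py` (two replicate 625 × 10000 px flumes, 189 windows
each, 199-replicate bootstraps, 1000-null type-I calibration in the
acceptance tests). These sizes give Monte-Carlo error comfortably inside
every asserted tolerance while keeping a full run in tens of seconds.
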