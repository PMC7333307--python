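# Methods

## Problem setting

A trellised vineyard is surveyed from above; structure-from-motion
photogrammetry yields a dense 3D point cloud and a DEM whose elevations
follow the highest visible surface (canopy tops over vines, soil in the
inter-rows). Both pipelines operate on a uniform polygon grid: rectangular
cells centered on the row axes, one inter-row wide and three intra-row
spacings (`3·ℓ_p`) long, so each cell holds exactly three plant slots.
Row geometry (endpoints, spacing, azimuth) is assumed known — from the
planting plan or the synthetic generator — and rows must be parallel
within 1°; automatic row detection is out of scope. Terminal row
remainders shorter than a full cell are dropped by default
(`keep_partial=True` keeps them with a prorated expected plant count).

## 2.5D surface-model method

1. **Slope mitigation.** A grey morphological opening with a flat
   structuring element wider than a vine row estimates the bare-terrain
   surface; subtracting it (top-hat) leaves height above local ground.
   The element half-width defaults to twice the inter-row spacing in
   pixels. The default footprint is a *square*, because a flat square
   opening is separable and costs O(n) independent of radius, while a
   disc at the default radius (1000 px at 5 mm GSD) is prohibitively
   slow; for slowly varying terrain both are equally valid ground
   estimators, and a decomposed-disc option is retained
   (`footprint="disk"`). For a monotone terrain ramp the opening is exact
   in the interior; residuals are bounded by slope × element width, and
   the element must fit inside the site or boundary bias appears.
2. **Soil/vine masking.** Otsu's threshold on the min-max-rescaled height
   image, quantized to 256 levels, with the within-class variance
   minimized by exhaustive search. The threshold is computed once for the
   whole field so that cells containing no canopy are not forced to split
   noise into two classes. Convention: soil = 1 (white), vine = 0 (black).
3. **Per-cell measurement.** Each cell is resampled onto its own
   row-aligned frame at native pixel size (nearest-neighbour sampling:
   interpolating across the soil/canopy step blends the classes and
   biases the statistics; with nearest sampling cell metrics are
   rotation-invariant to well under 2% at 5 mm GSD). Column sums of vine
   pixels give the thickness profile `δ_p(x) = δ(x)·dp·cos θ`; `θ` is the
   principal-axis tilt of the vine pixels (zero for a resampled cell; a
   degenerate single-column mask adopts θ = 0 with a warning, since
   cos(π/2) would annihilate the profile).
4. **Gaps and volumes.** Columns with `δ_p < 0.1 m` are gap columns.
   Sub-threshold runs shorter than 3 px (speckle) *or* shorter than
   `0.2·ℓ_p` are bridged before measuring: interruptions much shorter
   than a plant slot are porosity of a discontinuous canopy, not
   candidate missing plants, and counting them systematically inflates
   `L_v` on any site without a closed hedgerow (`min_gap_frac=0` restores
   the raw cumulated length). `N_ext = L_v/ℓ_p` is rounded half-up and
   clamped to the cell's plant count. Mean thickness `δ_m` averages
   `δ_p ≥ 0.1 m`; canopy height `dh` is the first quartile of per-row
   vine elevations minus the third quartile of per-row soil elevations
   (linear-interpolation quartiles, the common "type 7" rule) minus the
   0.8 m cordon, clipped at zero with a warning. Volumes:
   `V_p = dh·dL·δ_m` (mean plant, `dL = ℓ_p`) and `V_DEM = dh·dA` with
   `dA = N_px·(dp·cos θ)²`.

## 3D alphashape method

1. **Ground plane.** A consensus fit: 1000 random 3-point candidate
   planes (seeded; candidate scoring on a ≤30k-point subsample, final
   classification on the full cloud), constrained within 5° of vertical,
   with an inlier band of ±0.5 m. Plain inlier maximization is unreliable
   here — when canopy points outnumber ground points, horizontal strata
   through the canopy, or tilted "diagonal" planes on long sloped sites,
   can collect more inliers than the ground. The selector therefore
   scores `inliers − 2 × points_below_band`, exploiting the fact that the
   ground bounds the scene from below, and polishes the winner by
   iterated least squares on its inlier band. Non-inlier points above the
   plane become canopy; non-inlier points below it are discarded as
   reconstruction noise (counted in a warning).
2. **Alphashape volume.** Per cell (half-open clipping, so boundary
   points belong to exactly one cell), the canopy points are
   Delaunay-tetrahedralized and every tetrahedron with circumsphere
   radius ≤ α is kept; the volume is the sum of kept tetrahedra. α is a
   *length* (the MATLAB-style alpha radius, default 0.5 m), not the 1/α
   convention. α → ∞ gives the convex hull; fewer than 4 points or
   degenerate (coplanar) inputs give volume 0 with a warning. Geometric
   consequence worth knowing: an empty row section is carved out only if
   it admits an empty sphere of radius > α, so gaps shorter than ~2α
   (1 m) between canopy blocks are bridged and invisible to the method.
3. **Missing plants.** `v̄` is the mean alphashape volume of gap-free
   reference cells divided by the plants per cell. Reference cells come
   from, in order: an explicit `v_bar`; caller-supplied cell ids (e.g.
   cells where the 2.5D method saw no gap); or a volume-distribution
   heuristic (cells within 0.9 plant-shares of the 90th-percentile cell
   volume), which assumes dozens of cells and up to ~30% missing plants.
   A cell's plants-present is `cell_volume / v̄` rounded to the *nearest*
   integer and clamped to [0, 3]; missing = complement. Nearest rounding
   places the decision boundaries midway between the k-plant volume
   hypotheses; a ceiling rule (available as `rounding="ceil"`) puts the
   boundary exactly at the noiseless complete-cell volume, which turns
   symmetric volume noise into ~50% false negatives on single-missing
   cells. Both rules agree that a 3-slot cell below two average plant
   volumes flags at least one missing plant.

## Validation statistics

`linreg` fits observed on estimated volumes by OLS; `R²` is the squared
Pearson correlation and the reported RMSE is by default the *agreement*
RMSE between the paired values (distance from the 1:1 line), with the
regression-residual RMSE behind `rmse_kind="residual"`. Accuracy of a
missing-plant count is `(estimated − observed)/observed × 100` (signed,
2 decimals, half-up); the observed count is always the denominator.
`potential_plants` is density × surface rounded half-up — note that for a
3333 plants/ha × 1.9 ha site this gives 6333, and any differing published
tally is treated as an input where needed rather than recomputed.
`match_ground_truth` assigns surveyed gap positions to cells by the same
half-open rule and reports per-cell signed errors plus an unassigned
bucket.

## Synthetic vineyard generator

The generator emulates the *geometric* structure the methods rely on, not
photogrammetric radiometry. Terrain is a plane (default dip 0.03 m/m)
plus i.i.d. Gaussian noise (default σ = 1 cm, the typical vertical spread
of a high-overlap SfM cloud). Each vine is a rectangular slab centered on
the row axis: thickness CT (0.4 m), height CH (1.2 m) above a 0.8 m
cordon, length `canopy_length_frac·ℓ_p` (default 0.85 — vines do not fill
their slot wall-to-wall unless hedged/wrapped; this also keeps a missing
slot's empty span at `(2 − 0.85)·ℓ_p ≈ 1.04 m > 2α`, i.e. physically
carvable by the alphashape). Per-vine CH/CT/CL are drawn with a common
coefficient of variation (default 0.1); each slot is empty independently
with `missing_fraction`. Clouds sample slab *surfaces* (mirroring what
photogrammetry sees; a `solid_canopy` option exists for volume oracles)
at `point_density` (default 300 pts/m²; the real product is far denser,
but α = 0.5 m geometry is already stable at ~80 pts/m²), and the DEM
takes the highest surface per pixel at `dem_dp` (default 0.005 m/pixel)
plus noise. Two stress archetypes: `canopy_profile="top"` concentrates
foliage in the top `top_frac` of CH (palissage-like canopies, which a
nadir surface model inherently overestimates), and `overhang_frac > 0`
extends thin top-wire bridges from neighbours over a missing slot (the
hidden-gap condition: the DEM sees continuous canopy, the cloud still
sees the empty space below the wire).

What passing synthetic tests does *not* show: robustness to SfM artifacts
(doming, occlusion holes, outlier blobs), cover-crop vegetation in the
inter-row, curved or non-parallel rows, and real foliage texture. Results
on real surveys depend on those factors.

## Problem sizes and numerical choices

- End-to-end benchmarks run a 0.7 ha site (13 rows × 216 m at 2.5 × 0.9 m
  spacing, 3120 slots, 1040 cells, 15% missing) at 5 cm DEM resolution
  and 80 pts/m², 20 seeds; both pipelines stay within ±6% of the planted
  missing count, comfortably inside the ±20% band asserted, and both
  mildly overestimate (porosity false positives for 2.5D, low-volume
  cells for 3D).
- The brute-force alphashape oracle (all C(n,4) tetrahedra with explicit
  empty-circumsphere checks) is run on 100 random sets of 8–40 points;
  beyond that size the enumeration is no longer a practical oracle.
- Delaunay degeneracies: tetrahedra with |det| ≤ 1e-14 are treated as
  having infinite circumradius (excluded); Qhull failures on degenerate
  inputs yield volume 0 with a warning.
- Otsu ties are broken toward the lowest level (first argmin); both the
  implementation (vectorized cumulative sums) and the test oracle (plain
  loops) share this rule.
- PLY vertices are written in double precision: survey frames sit at
  10⁵–10⁶ m coordinates where float32 quantization (~0.1 mm/m·10⁵) would
  break sub-millimeter round-trips.
- Percentages in reports are rounded half-up to 2 decimals via decimal
  arithmetic on the shortest float representation.

## Known limitations

- LAS/LAZ clouds are not read; convert to PLY/XYZ first.
- The 2.5D method measures one cell at a time along its own axis; sharply
  curved rows would need denser row polylines than the two-endpoint
  representation used here.
- The v̄ heuristic fails on very small grids (< ~20 cells) or when more
  than ~30% of plants are missing; supply reference cells or v̄ then.
- With α = 0.5 m, gaps shorter than ~1 m along the row cannot be detected
  by the 3D method regardless of sampling density (see above); at
  ℓ_p < 1 m this is mitigated only by canopy not filling its slot.
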