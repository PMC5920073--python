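# Methods

## Problem and measurement model

Mature oilseed cotyledon cells store triacylglycerols in lipid droplets
(LDs) that a lipophilic dye such as Nile Red renders bright in confocal
z-stacks. A stack is a 3D scalar image on an anisotropic grid with pitch
(Δx, Δy, Δz); every quantity this package reports reduces to labeled-voxel
counting on that grid:

* droplet/cell volume = voxel count × Δx·Δy·Δz;
* equivalent diameter of a droplet = diameter of the equal-volume sphere,
  (6V/π)^(1/3) — droplets are treated as spheres and no caliper/Feret
  measure is attempted;
* per-cell lipid fraction VLD/VSC = (summed assigned droplet volume) /
  (cell label volume); field fraction VTLD/VTSF uses *all* droplet voxels
  over the full grid volume;
* cell spacing (CS) = mean over adjacent cell pairs of the minimum
  voxel-centre distance between the two cells' surfaces, minus one mean
  in-plane pitch.

The default calibration, 0.159 × 0.159 × 0.38 μm, corresponds to a
100× confocal acquisition of an 800 × 800 px (127 × 127 μm) field in
70 slices. Volumes always use the product Δx·Δy·Δz of the calibration
actually attached to the data; calibration mismatch between combined
volumes is an error, never a silent resample.

## Pipeline

1. **Preprocess** (`preprocess`): optional denoising (Gaussian by default,
   median available) and optional per-slice 2D Gaussian background
   subtraction for non-uniform illumination (per-slice because confocal
   shading varies with depth). The Gaussian default is deliberate: a
   symmetric blur preserves the half-level contour of a blob boundary, so
   downstream thresholded volumes stay unbiased, whereas a median window
   systematically erodes convex blobs (we measured ≈13 % volume loss on
   synthetic droplet fields with a 3³ median).
2. **Droplet segmentation** (`segment_droplets`): global Otsu threshold
   (256-bin whole-volume histogram; fixed-level override available), 3D
   connected components at 26-connectivity, physical-volume filtering of
   specks (default 0.05 μm³), and optional watershed splitting of merged
   droplets. Splitting markers are maxima of the anisotropy-aware Euclidean
   distance transform, kept if at least `min_sep_um` (default 3 μm) apart
   *and* at least half the component's EDT peak — the second condition
   stops digitization ripples on a single large sphere from seeding a
   spurious split, while two genuinely merged droplets of comparable size
   both pass it.
3. **Cell segmentation** (`segment_cells`): cells are bright and the
   intercellular matrix dark in the boundary channel. After smoothing and
   a wall cutoff (Otsu by default), a seeded watershed on the negated EDT
   delimits cells; sub-cutoff voxels stay background (label 0), so the
   matrix is excluded from VSC and remains available for the spacing
   measurement. Because these stacks span a single cell layer, the 3D EDT
   inside a slab-shaped cell plateaus at half the slab thickness; seeds are
   therefore detected on the 2D EDT of the in-plane projection and dropped
   at the cell column's mid-depth. Hand-segmented cell label TIFFs are
   accepted as a first-class alternative.
4. **Assignment and metrics** (`segment_cells.assign_droplets`,
   `morphometrics`): each droplet goes to the cell holding the most of its
   voxels (ties to the smallest cell id; plurality on background →
   unassigned). Per-cell statistics use only *integrated* cells — no voxel
   on any face of the stack, z faces included. Field totals (VTLD/VTSF)
   use every droplet, assigned or not. Conservation holds exactly:
   Σ per-cell VLD + unassigned droplet volume = VTLD.
5. **Reporting** (`report`): a line (replicates = fields) is summarized as
   mean and sample SD (n−1). Groups are compared on line means with
   Welch's unequal-variance t test (no homoscedasticity assumption); an
   exhaustive permutation test is available as a cross-check. Group means
   are unweighted means of line means.

### Cell spacing definition

The original measurements were made interactively with a 3D measurement
tool; no algorithmic definition exists to copy. The surrogate fixed here is
deterministic and oracle-testable: for each unordered pair of cells within
`max_gap_um` (default 15 μm), take the minimum physical distance between
surface-voxel centres and subtract one mean in-plane pitch to approximate
edge-to-edge rather than centre-to-centre distance (floored at 0); CS is
the mean over adjacent pairs. On slab constructions with a known gap the
surrogate is exact; on generated tessellations it recovers the prescribed
wall width within a few percent. It is documented as a surrogate, not
claimed identical to the interactive measurement.

## Synthetic fields

The generator emulates the imaged system so that every stage can be tested
against ground truth:

* **Geometry.** The physical field is 127 × 127 × 26.6 μm. The default
  desk-scale grid samples it at 256 × 256 × 40 voxels
  (0.496 × 0.496 × 0.665 μm pitch) so that a full field generates,
  renders and segments in seconds on one CPU; the spatial statistics
  (cell sizes, wall widths, droplet diameters) are expressed in μm and are
  grid-independent.
* **Cells.** n_cells (default 9, matching the "eight to ten integrated
  cells per field" regime) jittered-grid Voronoi seeds in a single layer;
  each voxel joins its nearest seed and is carved to background within
  wall_um/2 of a Voronoi bisector. The same carve is applied along the
  field faces so that the generated cells are integrated in the strict
  no-face-contact sense — without it a single-cell-layer stack would
  touch the z faces everywhere and no cell would qualify.
* **Droplets.** Per-cell counts are Poisson; diameters are lognormal in
  the log (μ, σ), truncated by rejection to a stated range; spheres are
  voxelized by the centre-in-sphere rule, placed largest-first by
  rejection sampling wholly inside their cell, non-overlapping with a
  minimum surface gap (default 1.0 μm — just above the largest voxel
  diagonal, so distinct droplets can never merge through 26-adjacency in
  a noise-free render; set `allow_contact` to exercise watershed
  splitting). Droplets that cannot be placed within the attempt budget
  are counted and reported, not silently dropped.
* **Rendering.** Two-level intensity (background 20, droplets +150;
  bright-field: cells 180, matrix 40), anisotropic Gaussian PSF specified
  in μm per axis (default σ = 0.25 μm in-plane, 0.4 μm axial) and
  converted to voxels per axis, then Poisson resampling and additive
  Gaussian read noise (σ = 3), clipped at zero.
* **Presets.** The HO-like and LO-like presets were calibrated once
  against the published phenotype ranges and then frozen: HO — 4 μm
  walls, 100 droplets/cell, diameters lognormal(ln 4.4, 0.38) truncated
  to [1.5, 8.5] μm; LO — 6 μm walls, 40 droplets/cell,
  lognormal(ln 4.9, 0.38) on [1.5, 9.5] μm. Note that truncation removes
  a substantial share of a lognormal's volume-carrying tail, so the
  realized mean droplet volume must be computed on the truncated law, not
  the closed form. Realized statistics (per-cell fraction ≈ 19–20 % HO
  vs 15 % LO, field fraction ≈ 13 % vs 8 %, TNLD ≈ 99 vs 40, CS ≈ 4.4 vs
  5.9 μm) fall inside the reported ranges for both groups.
* **Determinism.** One top-level seed; tessellation, placement and
  rendering consume independently spawned child streams, so identical
  specs give byte-identical outputs after serialization.

What the generator does **not** emulate: depth-dependent attenuation and
scattering, refractive-index aberrations, non-spherical or touching
droplets (unless enabled), irregular (non-convex) cell shapes, and
within-field gradients of oil content. Passing recovery tests therefore
demonstrates the correctness of the measurement machinery on
geometrically faithful scenes, not robustness to every real-world imaging
artifact; real bright-field channels in particular may need hand-made
cell labels, which the pipeline accepts directly.

## Numerical choices and degenerate inputs

* Otsu on a constant stack raises (no separable classes); fewer than two
  cells makes CS missing (NaN), not zero; an empty droplet set yields
  empty but valid tables.
* Size-class thresholds are strict inequalities: "large" means
  equivalent diameter strictly above 5 μm, "small class" strictly below
  100 μm³.
* Component labels are numbered from 1 in first-encounter raster (z, y, x)
  order, making label volumes reproducible and comparable across runs.
* Droplet connectivity is 26 (bright blobs must not fragment on diagonal
  contacts); cell regions use the watershed's 6-connectivity (cells are
  wall-separated, so face adjacency suffices).
* Welch on two degenerate (zero-variance) groups returns p = 1 when the
  means agree and p = 0 otherwise.
* A printed per-voxel volume constant of 1.11 × 10² μm³ sometimes quoted
  for this acquisition geometry is inconsistent with the stated pixel and
  slice pitches (0.159 × 0.159 × 0.38 ≈ 9.6 × 10⁻³ μm³); the package
  always computes Δx·Δy·Δz.

## Problem sizes used in tests

Unit tests run on small constructed volumes and a 16 × 96 × 96 synthetic
field; recovery and phenotype tests use the full desk-scale
40 × 256 × 256 geometry (one clean + one noisy recovery field, and three
HO-like + three LO-like fields). These sizes were chosen so the complete
suite runs in a couple of minutes on a single CPU while keeping every
physical parameter at its default value.

## Known limitations

* The per-line ± terms reported for the real lines cannot be reproduced:
  the replicate structure behind them (n = 10 fields vs n = 26 cells) is
  not public, so the package documents its own convention (sample SD over
  stated replicates) instead.
* VTLD includes droplets in partial border cells; per-cell metrics do
  not. Both conventions are fixed and tested, but other choices are
  defensible.
* Automated watershed on real bright-field data is best-effort; the
  `--cells` label-file path is the recommended route for difficult
  boundary channels.
* The interactive cell-interval measurement is approximated by the pair
  surrogate described above; systematic offsets of a fraction of the
  in-plane pitch are possible for oblique wall geometries.
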