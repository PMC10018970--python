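# Methods

`angioquant` quantifies the three-dimensional architecture of capillary
networks from fluorescence image stacks of labelled vasculature (or from
pre-traced centerline networks), and ships a synthetic vasculature generator
whose phantoms have exact ground truth.  This note records the models,
conventions and numerical choices the implementation rests on.

## Coordinate and unit conventions

Arrays are indexed `[x, y, z]`; voxel spacing is `(sx, sy, sz)` in µm; voxel
*centers* sit at `index × spacing + origin` with 0-based indices.  All
physical quantities are µm externally; voxel units appear only inside
kernels.  Multi-page TIFF is page-major `(z, y, x)` and the I/O layer
transposes at the boundary.  TIFF calibration metadata is treated as
advisory only — acquisition software routinely writes wrong values — so
spacing must be supplied explicitly and is recorded in a sidecar JSON with
every exported volume.

## Synthetic vasculature

Vessels are modelled as tapered capsules around polyline centerlines
(cylinders with spherical caps per edge, linear radius interpolation), with
union semantics at junctions; capsules give well-defined analytic volumes
and surface distances.  Four archetypes span the organized-to-chaotic range
of real microvascular beds:

* **parallel_fiber** — straight capillaries on an (optionally jittered)
  square lattice along z, joined by sparse perpendicular cross-links between
  lattice-adjacent fibers; muscle-like.  Cross-link planes are solved so the
  mean length of *rim-safe* segments (those a field-of-view filter keeps)
  equals the requested mean segment length.
* **random_arc** — curved segments (circular arcs with arc/chord =
  tortuosity, jittered per segment) grown as a rapidly-exploring random
  tree: each step grows from the existing node nearest a uniformly sampled
  target point, with node degree capped at 3.  This makes coverage
  space-filling and orientation isotropic, as in brain cortex capillaries.
  A small fraction of total length (default 8%) is placed as isolated
  fragments, mimicking vessels whose connections leave the field of view;
  the main filament always carries ≥ 90% of length.
* **planar_mesh** — a square-grid mesh of wide tubes in a plane near the top
  face, plus parallel perpendicular feeders to the bottom face; colon-like
  (a surface mesh over crypt vessels).  A retina-like variant is a
  two-layer stack of such meshes; it has no quantitative anchor and is not
  parameterized separately.
* **tumor** — the random-arc machinery with heterogeneous targets (growth
  aims at Dirichlet-weighted cluster hot-spots, 20% uniform so volume
  targets stay reachable), hard avascular exclusion spheres
  (reject-and-resample; tubes never intersect a void, so a void of radius R
  guarantees a tissue point at surface distance ≥ R), a configurable
  fraction of *short* segments dilated ≥ 2× in radius, and high tortuosity
  with large radius spread.

**Calibration.** When a target volume fraction is requested, organized
archetypes first solve the continuum relation (e.g. `vf = πr²/pitch²`) for
the lattice pitch; because line counts are integers this lands only
approximately, so radii are then trimmed by a few bounded multiplicative
steps (≤ ×1.6 total) against a fixed-seed Monte-Carlo estimate of the
capsule-union volume, converging within ~1–2%.  Arc archetypes calibrate
the segment count instead: the network is regrown with a damped count
update until the Monte-Carlo volume lands near target, keeping the best
build (the union volume is a noisy function of count because every regrowth
reshuffles overlaps); residual scatter is a few percent, larger (~10%) for
voided, clustered tumors.  Ground truth records the *measured* union
volume, never the target.

**Ground truth.** Every generator emits, alongside the graph: the union
volume fraction; the exact mean segment length and diameter (pure graph
arithmetic); the mean over rim-safe segments only (what a rim-filtered
tracing should recover); the closed-form maximal tissue-to-surface distance
`pitch/√2 − r` for unjittered lattices; and archetype bookkeeping (dilated
segment ids, diameter CV, mesh/feeder diameters).  A brute-force
point-to-capsule distance routine (`surface_distance_to_graph`) provides an
independent oracle for all of these on small instances.

**Rasterization.** A voxel is foreground iff its center lies inside the
capsule union (per-edge bounding boxes keep this linear in tube volume).
The degradation model for the intensity channel — Gaussian PSF blur,
background pedestal, Poisson counts, and "leakiness" (random per-point
radius perturbation imitating ragged tumor vessel surfaces) — is applied
only to a copy; the binary truth mask is always returned clean.  Not
modelled: depth-dependent attenuation, anisotropic PSF, stripe artifacts,
autofluorescence structure.  Recovery results on phantoms therefore
demonstrate correctness of the measurement chain, not robustness to every
real light-sheet pathology.

All randomness flows from the single `seed` in the spec; identical spec +
seed reproduces the graph bit-for-bit.

## Segmentation

3D median filter (radius in voxels, default 1, i.e. a 3×3×3 window; borders
mirror-padded), then a global threshold — explicit value (foreground ≥ t)
or Otsu's criterion with its foreground > t convention — then removal of
26-connected components *smaller than* 2000 voxels (boundary-inclusive:
exactly 2000 survives).  Connectivity is configurable; 26 matches the
visual continuity of thin tubes.  rPVV (relative perfused vessel volume) is
the foreground fraction of the mask, a voxel count ratio — no meshing.

## Tracing

**Skeletonization** is homotopic thinning: simple points — voxels whose
removal provably preserves digital topology, by the two topological numbers
(exactly one 26-component of foreground in the punctured 26-neighbourhood;
exactly one 6-component of background in the 18-neighbourhood touching a
face neighbour) — are removed sequentially in order of increasing
(anisotropy-aware) distance to background, anchoring curve endpoints
(voxels with ≤ 1 foreground neighbour).  Component count, loops and
cavities are preserved exactly, and the distance ordering keeps the curve
on the medial ridge.  The inner loop is numba-compiled.

**Graph building.** Skeleton voxels with ≠ 2 26-neighbours are node voxels;
adjacent node voxels are merged into one node at their centroid (thinning
produces 2–3 touching branch voxels per anatomical bifurcation).  Maximal
degree-2 paths between nodes become segments; a pure cycle becomes one
segment with coincident endpoints.  Two cleanup passes remove thinning
artifacts: terminal spurs shorter than 2× their radius are pruned, and
junction-to-junction bridges shorter than 2× their radius are contracted
into a single node (a voxel-grid X-crossing otherwise splits into two Y
nodes a few voxels apart); both factors are configurable, 0 disables.

**Radius.** Per centerline point, the radius is the interior Euclidean
distance transform of the mask sampled at the skeleton voxel, plus
0.38 × the local transverse voxel pitch — the expected distance between a
voxel center and a uniformly placed true axis, evaluated from the local
polyline tangent so anisotropic stacks are handled.  Endpoint samples sit
inside junction blobs where the EDT overestimates; they are excluded from
the per-segment diameter average when ≥ 2 interior samples exist.
Cross-sectional fitting is deliberately not used.

**Per-segment measures.** Length is the polyline arc length in µm (beware:
for strongly curved vessels at coarse spacing, the voxel staircase inflates
arc length by up to ~10–20%; straight and gently curved tubes are
unaffected — a known limitation).  Straightness is chord/arc in (0, 1], 0
(flagged) for closed loops.  Orientation is the chord's XY-plane angle,
axial (mod 180°), in (−90°, 90°].  Orientation distributions can be
re-centered on their modal direction (5° bins; the modal bin is refined to
the axial circular mean of its members, so an already-aligned sample
centers exactly at 0°); spread is summarized by the axial circular standard
deviation.

**Rim filter.** Segments with an endpoint within one voxel *plus twice
their radius* of a volume face are flagged and excluded from statistics:
the imaging field of view necessarily cuts vessels at its rim, and thinning
retracts the skeleton tip of a cut tube inward by about one radius, so a
bare one-voxel test would miss most rim casualties.

## Extravascular distance analysis

Exact Euclidean distance from every tissue voxel center to the nearest
vessel voxel center, honoring anisotropic spacing
(`scipy.ndimage.distance_transform_edt` with sampling).  Vessel-interior
voxels are excluded from the distribution by default — the supply question
concerns tissue, and the interior zeros would deflate every percentile —
with a flag to include them.  RM10 = P100 − P90 of the distance
distribution: the range of the farthest 10% of tissue, low when vessels are
homogeneously spaced.  P90 uses linear interpolation between order
statistics (the convention matters at these sample sizes and is fixed);
P100 is the maximum.  Statistics run on float distances; the 8-bit heatmap
channel (grey 0–255 linearly encoding 0–max, half-up rounding, decode error
≤ max/510) is an export format, with a quantized-statistics mode available
for workflows that read percentiles off an 8-bit histogram.

## Summary statistics

**KDE areas.** For a paired per-segment cloud (canonically mean diameter D
vs straightness S), a Gaussian product-kernel density with per-axis Scott
bandwidths (`σᵢ·n^(−1/6)`) is evaluated on a 256² grid padded by 3
bandwidths.  The highest-density-region threshold is, by default, the
(1 − α) quantile of the density evaluated at the data points themselves;
the region then covers α of the underlying distribution and the area
estimate is free of kernel-smoothing inflation — for a circular bivariate
normal the 50% area converges to `2π·ln2·σ²` (verified to < 5% at
n = 5000).  The alternative `grid_mass` threshold (sort grid densities,
accumulate mass) measures the smoothed density's own HDR and runs
`≈ n^(−1/3)` large; it is provided for comparison.  Small KDE₅₀(D/S) areas
indicate hierarchical, organized vasculature; tumors smear mass across wide
D and S ranges.

**Feature table and PCA.** One row per sample: rPVV, RM10, mean/SD of
length, diameter and straightness, orientation circular SD, KDE₅₀ and
KDE₉₀(D/S) areas, mean/max extravascular distance, segment density (per
10⁶ µm³), filament count.  Rim-flagged segments are excluded everywhere.
PCA z-scores features, drops constants (warning) and incomplete rows
(warning), and ranks variables by the loading-vector norm in the PC1–PC2
plane — the arrows a biplot draws longest.

**Group comparison.** Two-sided two-sample t-test preceded by an F-test on
the variances (α = 0.05): pooled-variance test if equality is not rejected,
Welch otherwise; the variant used is always reported.  Zero variance in
both groups with equal means returns p = 1, flagged.  No multiplicity
adjustment by default; Holm can be applied downstream.

**Evans-Blue utility.** `miles_correction(a620, a740) = a620 − (1.426·a740
+ 0.030)` removes co-extracted hemoglobin bleed-through at 620 nm before
reading dye concentrations off a standard curve.

## Problem sizes used in tests and benchmarks

Recovery benchmarks run at 200³ voxels (0.5×0.5×1 µm) for volume-fraction
recovery, 200×200×320 µm at 1 µm isotropic (≥ 300 interior segments) for
segment-length recovery, and 600×600×36 µm at 1 µm for mesh pitch; the
deterministic distance constructions are single lattice cells.  Oracle
suites use ≤ 25³ grids (where O(n²) brute force is exact) and n = 5000
point clouds.  Discrimination checks pair organized and tumor networks at a
matched 3.5% volume-fraction target across 10 seeds in 150³ µm domains.

## Known limitations

* Curved-vessel arc lengths carry voxel-staircase inflation at coarse
  spacing (no sub-voxel centerline smoothing, by design).
* The EDT radius estimate assumes roughly circular cross-sections; strongly
  elliptical lumina are underestimated.
* Graph-input mode computes rPVV on a rasterization of the graph's bounding
  domain, which is not the acquisition FOV; its volume fractions are not
  comparable to mask-mode values (segment statistics are, within ~5%).
* SWC export writes one spanning tree per filament: cycles are dropped
  (GraphML is lossless), and re-importing merges chains through degree-2
  nodes.
* The generators emulate geometry and first-order imaging noise, not
  hemodynamics, perfusion state, or light-sheet-specific artifacts.
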