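# Methods

Definitions, parameter defaults, numerical choices and limitations of the
`percwear` measurement pipeline. All lengths are millimetres, areas cm².

## 1. Orientation and plane assignment (`surface_io`)

A tool scan is a point cloud (optionally triangulated; all measures are
point-based). `orient_model` rotates it rigidly into the analysis frame:

1. **Principal axes.** Eigen-decomposition of the point covariance; the
   largest extent goes to Y, the middle to X, the smallest (slab thickness)
   to Z. Signs are fixed deterministically (favouring the identity for
   already-oriented clouds) so repeated runs give identical frames.
2. **Up side.** With `up_hint`, the indicated side faces +Z. Otherwise the
   side whose outermost 10%-thickness slab holds *fewer* points faces up:
   concave damage pulls surface points below the face plane, thinning the
   damaged side's extreme slab. This is a stand-in for the field protocol
   of laying the visibly damaged surface upward.
3. **Leveling.** Principal axes of a damaged block are skewed a few degrees
   by the carved material; a residual tilt of the active face makes a
   planar slope mimic a depression at the downhill edge of a TPI
   neighbourhood. A trimmed least-squares plane is fitted to the top 20%
   slab (residuals below median − 3×MAD — i.e. pit points — are dropped,
   two iterations) and the cloud is rotated so that plane is level.
4. **Plane labels.** Per-point normals (smallest axis of the 12-neighbour
   covariance) are matched to the six box axes within 30°; opposite faces
   are separated by position relative to the box centre. Points on edges
   and steep pit walls stay unlabelled. If no "A" points result, the top
   decile of z is used as a fallback active face.

The **convex hull** of the full cloud is the depth reference. For a point
inside a convex polytope, the distance to the boundary equals the largest
of its signed distances to the facet planes, so `signed_distance` is exact
(scipy `ConvexHull` equations; verified in tests against an independent
per-facet mesh-distance oracle).

## 2. Pit detection (`pit_morphometry`)

**TPI.** For each active-plane point, TPI = z − mean z of planimetric
neighbours within `tpi_radius` (default 20 mm), excluding the point itself.
Points with fewer than 5 in-radius neighbours are undefined (NaN), not
extrapolated. TPI is invariant to adding a constant elevation.

**Threshold.** Depression mask = TPI < −τ with τ = max(0.3 mm, 3×MAD of
the defined TPI values). The floor keeps flat, noiseless surfaces from
producing spurious detections; the MAD term adapts to grain noise.

**Segmentation.** Connected components of the mask under a planimetric
linkage radius, computed via a KD-tree pair query and sparse connected
components. The default linkage is 4× the median nearest-neighbour
spacing: uniformly sampled scans form a random geometric graph whose
connectivity needs a multiple of the mean spacing, while grid-like scans
connect at 2× (the parameter is exposed for such scans). Components whose
minimum-area oriented bounding box is shorter than `min_pit_length`
(default 10 mm, the discrete-pit size criterion) are discarded. Regions
are disjoint and maximal by construction; ids are assigned in (y, x)
centroid order, so they are stable across runs.

**Depth.** Signed deviation of member points from the convex hull:
`depth_mm` (mean member deviation) and `depth_max_mm` (deepest member).
Negative = below the hull. Because the hull rides on the highest points,
grain noise biases measured depths slightly deep (≈ +0.1–0.5 mm at
σ = 0.1–0.25 mm noise); the pit-recovery acceptance test bounds the
resulting |depth_max| error at 15% under its stated conditions.

**Gradient.** Mean over member points of the slope (rise over run) of a
least-squares plane fitted to the planimetric `fit_radius` neighbourhood
(default 2 mm). Only points of the region's own plane enter the fits —
other faces of the block share the same planimetric footprint and would
corrupt them. Exact on ramps (gradient = tan θ) and matches an analytic
quadrature oracle on spherical caps within 2%.

**Roughness.** Mean absolute orthogonal distance of each member from the
total-least-squares (SVD) plane of its 3D `window` neighbourhood (default
0.5 mm, requiring ≥ 4 points). Zero on planes; insensitive to long-wave
form (a 50 mm-wavelength, 2 mm-amplitude undulation reads < 0.05 mm).

**Adaptive windows.** Desk-scale scans are far sparser than field scans
(25 vs 25 000 points/cm²). With `adaptive_windows` (pipeline default) the
roughness window and gradient fit radius are widened to at least 2.5× the
median point spacing so the neighbourhood fits are always supported.

## 3. Planform measures (`planform`)

The active-surface **outline** is an alpha shape (union of Delaunay
triangles with circumradius ≤ alpha) of the plane-A points projected to
XY; default alpha is 5× the median point spacing. **Pit polygons** use 4×
the spacing — tight enough to keep concavity, loose enough that uniformly
sampled interiors do not shred into fragments. `alpha = inf` gives the
convex hull; holes are filled (the outline is the exterior ring).

Per pit: polygon area (cm²), minimum-area rotated-rectangle length and
width (shapely; verified against a rotating-calipers oracle), and polygon
centroid. Per surface:

* **PA** = 100 × area(union of pit polygons ∩ outline) / area(outline) —
  overlapping pits are not double-counted;
* **D** = pit count / outline area (pits per cm²);
* **DAC** = distance from each pit centroid to the outline centroid;
* **DAE** = distance from each pit centroid to the nearest outline edge;
  both reported as min/mean/max per surface.

Because the polygon boundary passes through the outermost sampled points,
planform areas underestimate the true aperture by roughly half the point
spacing in radius; this discretisation bias is visible at desk-scale
densities and negligible at field densities.

## 4. Assemblage statistics (`assemblage_stats`)

* Descriptive blocks: min, max, mean, sample s.d. (n − 1 denominator; NaN
  for a single observation); missing values are excluded row-wise.
* **Mann–Whitney U**, two-sided; U reported as min(U₁, U₂) with both kept.
  The p-value is exact (full null distribution) when the pooled sample has
  ≤ 12 untied observations, otherwise a tie-corrected normal approximation
  with continuity correction; `method` can force either. The exact path is
  verified against full enumeration and its type-I rate is calibrated in
  the acceptance suite.
* **Kruskal–Wallis** with tie correction, p from chi-square (k − 1 df).
* **Dunn's post hoc** z tests with the Σ(t³−t)/(12(N−1)) tie term,
  Bonferroni-corrected by m = k(k−1)/2 (capped at 1).
* **PCA** on the correlation matrix by default (the damage variables mix
  counts, percentages and mm; covariance PCA is available via
  `standardize=False`). Computed by SVD; component signs fixed so each
  component's largest-magnitude loading is positive; incomplete rows are
  dropped with the count reported.
* `compare_assemblages` runs the U test per damage variable
  (n_use_wear, PA, D, DAC min/mean/max, DAE min/mean/max) and a pooled,
  labelled PCA. Significance is assessed at α = 0.05 throughout.

## 5. Reference tables and synthetic generator (`synthetic`)

Two small CSVs ship with the package: per-tool dimensions, raw material
and nut species (11 hammerstones, 7 anvils; anvil thickness/volume/mass
were not recorded in the field and stay missing), and the macro use-wear
overview (damage flags, discrete use-wear counts, active-plane counts,
with one "indeterminate" count preserved as such). The two sources spell
one tool id differently; records are joined on a normalised key. These
tables reproduce the published descriptive statistics and Kruskal–Wallis
values (acceptance criteria 1–2). Known text/table tensions in the source
are preserved as tabulated, not edited.

**Surface generator.** A tabular block is sampled uniformly per face
(sides at quarter density; they only close the hull). Pits of known
centre, radius and depth are carved into the top face with a spherical-cap
(default) or truncated-Gaussian profile; Gaussian grain noise is added
along each face's outward normal with per-material amplitudes (GD 0.05,
Q 0.15, MG 0.25 mm — monotone in the qualitative grain-size ranking; the
magnitudes are free choices). The default sampling density (1000
points/cm²; assemblages use 25) keeps runs desk-sized — field scans are
~25 000 points/cm² and the density is a spec field. Every random step is
seed-driven; identical seeds give bitwise-identical clouds, and each
surface returns its ground-truth pit table.

**Assemblage generator.** Two groups with configurable effects; defaults
follow the reference per-group figures: hammerstones average 1.3 pits of
median depth 4.31 mm placed centrally on ~224×178×117 mm blocks, anvils
11.6 pits of median depth 15.48 mm dispersed over ~644×345×150 mm blocks.
Counts are Poisson; depth and radius lognormal; placement is a per-axis
truncated normal with rejection sampling that keeps centre separation ≥
0.9×(r_i + r_j) (crowded faces accept overlap — closely spaced pits do
merge on heavily used anvils); depth is capped at min(1.5×radius,
0.4×thickness). `scale` shrinks blocks *and* pit geometry for fast runs,
leaving counts and group contrasts intact. Alongside the sampled clouds,
an analytic per-tool summary (counts, PA from exact circle unions,
DAC/DAE, depths) is computed from the ground truth so statistical
behaviour can be tested cheaply at large n.

## 6. Pipeline and CLI (`pipeline`, `cli`)

`run_pipeline` reads every PLY/OBJ/XYZ in the input directory in sorted
order, orients any unoriented model, analyses plane A, and writes
`pits.csv`, `surfaces.csv`, `pipeline.log`, and — when a metadata CSV
splits the tools into exactly two `tool_type` groups — `comparison.csv`
and `pca_scores.csv`. The log records every effective parameter value and
all row exclusions; stage errors carry the tool id. Identical config +
seed gives byte-identical CSVs. TOML configs reject unknown keys.

CLI subcommands (`percwear …`): `simulate`, `detect`, `measure`,
`planform`, `stats`, `compare`, `report` (alias `run`). Every stage reads
and writes plain CSV so any step can be re-run from intermediates.

## 7. Limitations

* Detected pit regions are the TPI-depression *cores*, not full apertures:
  PA from detection is systematically below the ground-truth aperture
  coverage (e.g. 2.95% measured vs 4.54% true in the README example). The
  contrast between groups is preserved, which is what the assemblage
  comparisons use.
* The convex-hull depth reference rides on noise peaks, biasing depths
  slightly deep; bounded at desk scale by the acceptance tests.
* The up-side heuristic assumes damage is concave and on one face; tools
  damaged on both faces, or scans of only part of a tool, need `up_hint`.
* Plane assignment excludes steep pit walls (> 30° off the face axis), so
  wall points do not contribute to TPI or gradient fits on plane A.
* The generator does not model flake detachment scars, crushing texture
  beyond white noise, base curvature, or wooden anvils.
* Statistical routines assume independent observations; tools contributing
  several active planes are treated per-surface by the pipeline.
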