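# Methods

`canopy3d` extracts leaf-level and canopy-level structure from
multi-station terrestrial-lidar point clouds of a crop canopy.  This note
describes the models, the virtual scanner the package validates itself
against, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Conventions

All geometry is in meters, in a right-handed frame with z up (the zenith
axis).  Leaf labels are positive integers; 0 is reserved for
"unassigned / not a leaf".  Leaf inclination at a surface point is the
zenith angle of the surface normal there: 0° for a horizontal patch, 90°
for a vertical one.  Scanned leaf sheets have no consistent inside/outside,
so normals are only defined up to sign; every angle the package reports
uses the upward-folded normal, i.e. θ = arccos |n_z| ∈ [0°, 90°].

## Registration

Stations are co-registered with classic point-to-point ICP: alternate
nearest-neighbour correspondence search (k-d tree) with the closed-form
least-squares rigid fit (Kabsch/Horn; SVD of the cross-covariance with the
reflection branch corrected) until the correspondence RMSD improves by
less than `tolerance` (default 1e-6 m, three orders below a millimeter
range resolution) or `max_iterations` (50) is reached.  Because stations
see different sides of the canopy, correspondences beyond `max_distance`
are dropped each iteration and, of the survivors, pairs beyond 3× the
median pair distance are trimmed.  The transform is refit from the
original source coordinates each iteration, so the result is the composed
source→target motion without incremental drift.

Initialization comes from the surveyed scan geometry: stations nominally
sit on a circle around the canopy, so the pair transform is an azimuth
rotation about the canopy's vertical axis (`azimuth_init`, pivot at the
working range along the viewing axis).  Identity initialization works only
for clouds that already roughly coincide.

The pipeline registers stations 2..n onto station 1 (star topology) in two
passes: a coarse pass with `max_distance` = 5 cm to absorb the
tripod-placement error of the initialization, then a refinement pass at
1 cm.  The second pass matters: with partial overlap, far pairings in the
5 cm band bias the fit by several millimeters.  No global multiview
relaxation is performed.

Practical accuracy limit: ICP on smooth, sparse foliage is well
constrained only when the scene offers surfaces in many orientations.  On
scenes of a handful of isolated leaves the transform can slide
centimeters along the sheets without changing the RMSD; the benchmark
therefore always registers full canopies.

## Multi-view fusion

After registration each leaf's merged points are averaged over a square
grid (cell 3 mm ≈ 1.5× the native point spacing) aligned with the leaf's
best-fit plane (`fuse_leaf_points`).  The averaging extends without limit
along the plane normal, which collapses (i) the independent range noise of
overlapping stations and (ii) the slightly offset duplicate surfaces left
by residual registration error (a few mm).  Without this step,
triangulating raw merged clouds inflates leaf areas by 10–30%: vertex
noise at the 1 mm level over 2 mm spacing roughens the sheet, and surface
area is monotone in roughness.  A cubic `voxel_downsample` is also
provided for generic clouds; the plane-aligned version is what the
pipeline uses because it preserves in-plane resolution while smoothing
only the out-of-plane direction.

## Leaf meshing

A segmented leaf is a near-2.5-D sheet.  `triangulate_leaf` fits the
least-squares plane (principal axes of the centered points), projects onto
it, Delaunay-triangulates the 2-D projection (Qhull), and lifts the faces
back onto the original 3-D points — every vertex is a measured (or fused)
point; no interpolated vertices are invented.  The Delaunay triangulation
of a projected outline necessarily bridges concavities and holes; faces
with an edge longer than `edge_factor` × the median nearest-neighbour
spacing are removed afterwards.  Faces below 1e-12 m² are dropped during
triangulation rather than erroring downstream.  Collinear input raises a
degenerate-geometry error; the PCA projection is safe for sheets whose
normals stay within ~60° of the fitted plane's normal, which holds for the
leaves considered here.

`edge_factor` defaults: 3 for `MeshingParams` in isolation (isotropically
sampled single-view clouds), 12 in the pipeline.  The difference is
deliberate.  Beams spanning zenith 94° ± 13° hit near-horizontal leaves at
grazing incidence, stretching the on-surface point spacing several-fold
along one axis; filtering at 3× the median nearest-neighbour spacing
deletes most of such a leaf's faces (up to 60% of its area in our
measurements), whereas 12× keeps the genuinely sampled surface connected
while still cutting hull bridges across gaps larger than ~3.5 cm at the
default fusion cell.  Because the leaf planforms are convex, bridging
moderate sampling gaps reconstructs surface that is actually there; for
multi-lobed real leaves a smaller factor is advisable.

One-sided leaf area is the mesh surface area, Σ ½‖(v₁−v₀)×(v₂−v₀)‖ — a
leaf is modeled as a zero-thickness sheet.

## Normals and inclination

Face normals come from the cross product, folded upward.  Per-vertex
normals (`point_inclination_angles`) are the area-weighted average of
adjacent folded face normals; vertices left isolated by the edge filter
are reported as missing (NaN), never as 0°.

For angle measurements on scan-derived meshes the package additionally
offers radius-based normals (`vertex_normals_radius`, default support 8 mm
in the benchmark): the normal at a vertex is the principal eigenvector of
the area-weighted dyadic sum Σ wᵢ nᵢ nᵢᵀ over all faces within the radius.
Two reasons.  First, a single 3 mm facet's normal is noise-dominated;
averaging over a patch far smaller than the leaves' bending radius (≥5 cm)
buys a large noise reduction at negligible curvature bias.  Second, the
dyadic mean is invariant to the per-face sign ambiguity: where a leaf
folds through vertical, upward-folded normals become antipodal in the
horizontal plane and a plain vector average cancels toward a spuriously
vertical direction (we observed isolated 70°+ errors from exactly this
before switching).  Sampled-point angles interpolate vertex normals
barycentrically, with the same dyadic rule.

## Canopy descriptors

* Per-leaf records: mesh area, area-weighted face-centroid height, face
  count.
* LAD profile: each face's area is assigned to the horizontal layer
  (default thickness 0.20 m) containing its centroid's z; LAD_k = assigned
  area / (footprint_area × thickness).  Faces outside [z_min, z_max] go to
  an overflow diagnostic, never silently dropped, so
  Σ LAD·t·footprint + overflow = Σ mesh areas exactly.  Centroid
  assignment (rather than splitting triangles at layer boundaries) biases
  each face by at most one face height — negligible for mm faces in 20 cm
  layers.  `footprint_area` is a required input: it is the horizontal
  cross-section of the analyzed region and cannot be inferred from the
  meshes.
* LAI is the vertical integral Σ LAD·thickness; by construction it equals
  total assigned area / footprint and is invariant to layer refinement.
* Inclination statistics per leaf: n points (default 20) sampled uniformly
  by area (seeded), the containing face's angle per sample, mean and
  population standard deviation.  The sampling law (area-uniform, not
  vertex-uniform) and the population std are package conventions.
* MAPE = (100/n) Σ |estᵢ − actᵢ|/actᵢ validates estimated areas against
  reference ones.

## The virtual scanner

No public scan data exists for this kind of canopy, so validation runs on
synthetic scenes with exact ground truth.

**Leaves** are elliptical planforms (length L, width W) bent sinusoidally
along the midrib with amplitude A: s(u,t) = (uL, t·w(u), A sin πu) in the
leaf frame, pitched down by the base inclination and yawed to an azimuth.
This is the simplest family with closed-form normals
(∝ (−Aπ cos πu, 0, L)), nonzero double curvature in world space, and a
cheap area oracle; the quadrature uses the substitution u = (1−cos θ)/2 to
remove the square-root planform endpoints (200×200 nodes, ~1e-10
relative).  Compound leaflets, serrations and midrib twist are not
modeled.

**Canopy defaults** (generate_canopy): 30 leaves, 1.8 m tall canopy,
0.45 m × 0.45 m footprint (≈0.36 m³ analyzed volume); lengths uniform
0.05–0.25 m, width/length 0.35–0.6, bend amplitude 0.05–0.2 of length,
base inclination uniform 0–75°, azimuth uniform, bases uniform in the
footprint at heights 0.3–1.7 m.  Truth LAD/LAI comes from the same
quadrature binned into 0.20 m layers.

**Scanner defaults** (ScannerConfig): 3 stations at azimuths 0/120/240° on
a 5.0 m circle at 1.3 m height, beams on a regular angular grid (0.4 mrad
step ≈ 2 mm spacing at range) spanning zenith 81–107° (94° ± 13°),
first-return only (Möller–Trumbore against a ≤4 mm ground-truth
tessellation, nearest hit per beam → occlusion), Gaussian range noise
σ = 1 mm along the beam; angular jitter is not modeled.  Station
placement jitter (azimuth ±1°, range ±2.5 cm, height ±1 cm, uniform)
emulates tripod setup error: it is what makes the nominal-geometry ICP
initialization inexact, and the true jittered transforms are exported so
registration can be scored against truth.  The regular angular grid means
point density falls with range and incidence angle, as for a real
galvano/stepper scanner.  Beam intersection exploits the grid: each truth
triangle is rasterized to its angular bounding box and tested only against
those beams, which keeps a ~500k-beam station scan at a few seconds.
Intensity, beam divergence, multiple returns and stems are not simulated.

## Benchmark experiments

* Leaf-area accuracy (`leaf_area_trial` / `leaf_area_benchmark`): for each
  seed, generate a 30-leaf canopy, scan from 3 stations, register from the
  nominal initialization, fuse, mesh, and compute the MAPE of mesh areas
  against quadrature truth over the reconstructed leaves; the benchmark
  reports the median over 20 seeds.  Typical result ≈3.5%, dominated by
  occlusion/grazing underestimation on a few unfavourably oriented leaves,
  with noise inflation largely removed by fusion.
* Inclination accuracy (`inclination_trial`): reconstruct the standard
  canopy, pick 5 leaves at random from the reconstructed set (as one picks
  leaves from the meshed canopy in a field campaign — stand-alone
  few-leaf scenes would instead measure ICP's sliding degeneracy), draw 60
  area-uniform samples allocated by mesh area, and compare each sample's
  mesh-derived angle (radius-based dyadic vertex normals) with the
  analytic normal at the nearest parametric surface point.  Typical mean
  absolute error ≈0.5–0.8°.

Problem sizes (30 leaves, ~25k points/station, 20 seeds) keep the full
benchmark under a minute on one CPU while using the scanner's native
resolution; they were chosen as the smallest scenes that exercise
occlusion, partial overlap and grazing incidence simultaneously.

## What passing the benchmark does and does not show

The generator produces smooth, convex-planform, one-sided sheets with
ground-truth segmentation labels.  Real canopies add compound and serrated
leaves, motion during the scan, mixed/edge returns, segmentation errors,
stems and fruits — none of which the benchmark exercises.  Results on
synthetic scenes therefore bound the geometric pipeline (registration,
fusion, meshing, trait extraction) under the stated scan geometry and
noise, not the end-to-end field measurement.  LAD/LAI values additionally
inherit whatever occlusion bias the scan geometry imposes on total
recovered area; the conservation identities guarantee internal
consistency, not completeness.

## Known limitations

* Point-to-point ICP only; no point-to-plane variant, no global multiview
  adjustment, no feature-based coarse alignment.
* Meshing assumes near-2.5-D leaves; folded-over leaves (normal deviation
  > ~60° from the PCA plane) would alias in projection.
* The long-edge filter is a single global threshold per leaf; strongly
  anisotropic sampling is handled by a generous factor rather than an
  anisotropic metric.
* Layer assignment by face centroid; exact triangle splitting at layer
  boundaries is not implemented.
* The simulator's leaf model is single-lobed; tomato-like compound
  leaflets are out of scope.
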