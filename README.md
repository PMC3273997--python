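# canopy3d

Canopy structure from multi-station terrestrial lidar: co-register
per-station point clouds of a crop canopy, reconstruct each segmented leaf
as a triangle mesh, and extract one-sided leaf areas, the vertical leaf
area density (LAD) profile, the leaf area index (LAI), and leaf
inclination angles — together with a virtual scanner that generates fully
ground-truthed synthetic scans for validation.

## Who this is for

Plant-phenotyping and canopy-structure researchers working with
high-resolution (mm-class) portable scanning lidar.  Non-destructive,
leaf-level structure — each leaf's area and its inclination-angle
distribution, plus the canopy-level LAD/LAI summaries — supports crop
management questions (light interception, water-stress diagnosis via leaf
droop, growth monitoring) that destructive sampling or spatially
aggregated indices cannot.

## The method

1. **Registration.**  Clouds from stations placed around the canopy (3
   stations 120° apart at ~5 m by default) are brought into one frame by
   point-to-point ICP: alternate nearest-neighbour correspondences with
   the closed-form Kabsch/Horn rigid fit `min Σ‖R·sᵢ + t − gᵢ‖²`,
   initialized from the surveyed station geometry, with distance-based
   outlier rejection for partial overlap.
2. **Fusion.**  Each leaf's merged points are averaged over a 3 mm grid
   aligned with the leaf's best-fit plane, collapsing range noise and
   residual registration offset between overlapping stations.
3. **Meshing.**  Each leaf (segmentation labels are taken from the
   simulator truth or supplied with the data) is projected onto its
   principal plane, Delaunay-triangulated, and lifted back to 3-D;
   over-long bridging faces are filtered.  One-sided leaf area is the sum
   of face areas ½‖(v₁−v₀)×(v₂−v₀)‖.
4. **Traits.**  LAD_k = (leaf area in layer k)/(footprint area × layer
   thickness) with 0.20 m layers; LAI = Σ LAD_k·thickness.  Leaf
   inclination at a point is the zenith angle of the upward-folded surface
   normal, θ = arccos|n_z| ∈ [0°, 90°]; per-leaf statistics use 20
   area-uniform surface samples.
5. **Validation.**  The virtual scanner casts a regular angular beam grid
   (~2 mm spacing at 5 m, zenith span 94° ± 13°, first return only, 1 mm
   Gaussian range noise) at parametric leaves with closed-form normals and
   quadrature-exact areas, so every estimate can be scored against truth.
   Mesh-derived leaf areas come out with a median MAPE of ≈3.5% and
   sampled inclination angles with a mean absolute error well under 1°.

See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

Run the full synthetic benchmark pipeline (simulate → register → fuse →
mesh → traits):

```sh
$ canopy3d run --seed 1 --out demo_run
30/30 leaves reconstructed; leaf-area MAPE 3.16%; LAI 1.307 (true 1.302)
```

All 30 leaves of the simulated canopy were recovered through the
three-station scan; their mesh areas deviate from the generator's true
areas by 3.16% on average, and the LAI integrated from the estimated LAD
profile (1.307 m² m⁻²) matches the quadrature truth (1.302 m² m⁻²) to
better than half a percent.  `demo_run/` now contains the per-station
clouds (`station1..3.ply`), ground truth (`truth.json`), the registered
merged cloud, per-leaf meshes, and two tables.  The per-leaf table starts:

```
leaf_id,area_m2,centroid_z_m,n_faces,mean_incl_deg,std_incl_deg,true_area_m2
1,0.010364251,1.5980896,2069,35.510991,13.712424,0.010403871
2,0.0090305923,0.99156121,1946,62.748943,14.145606,0.0087878896
```

Leaf 1 is a 104 cm² leaf at 1.60 m height whose mesh recovered its area to
0.4%; its 20 sampled inclination angles average 35.5° with a 13.7° spread —
leaf angle genuinely varies across a curved leaf surface.
`report.json` adds registration diagnostics (final ICP RMSD was 1.8 mm for
both station pairs here) and the LAD profile.

The stages are also available separately (`canopy3d simulate`, `register`,
`mesh`, `traits`) and as library functions:

```python
import canopy3d as c3

leaves, truth = c3.generate_canopy(n_leaves=30, seed=1)
clouds, true_transforms = c3.simulate_scan(leaves, c3.ScannerConfig(seed=1))
res = c3.icp_register(clouds[1], clouds[0], init=c3.azimuth_init(120, (5, 0, 0)))
print(f"station 2 → 1: rmsd {res.rmsd * 1e3:.2f} mm in {res.iterations} iterations")
```

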