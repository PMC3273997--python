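"""Ground-truthed benchmark experiments for the full pipeline.

These functions run the virtual scanner end to end and score the
reconstruction against the generator's analytic/quadrature truth:

* :func:`leaf_area_trial` — per-scene mean absolute percent error (MAPE)
  of mesh-derived leaf areas for a 30-leaf canopy scanned from 3 stations;
* :func:`leaf_area_benchmark` — the median of that MAPE over many seeds;
* :func:`inclination_trial` — mean absolute error of mesh-derived leaf
  inclination angles against the closed-form surface normals, over surface
  points sampled uniformly by area.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .meshing import MeshingParams
from .pipeline import DEFAULT_FUSE_CELL_M, reconstruct_leaves, register_stations
from .registration import apply_transform
from .simulate import ScannerConfig, generate_canopy, simulate_scan
from .traits import mape, sample_inclinations

__all__ = [
    "reconstruct_synthetic_scene",
    "leaf_area_trial",
    "leaf_area_benchmark",
    "inclination_trial",
]


def reconstruct_synthetic_scene(
    seed: int,
    n_leaves: int = 30,
    height: float = 1.8,
    footprint: tuple = (0.45, 0.45),
    scanner: ScannerConfig | None = None,
    meshing: MeshingParams | None = None,
    fuse_cell: float = DEFAULT_FUSE_CELL_M,
):
    """Simulate, register, fuse and mesh one synthetic canopy.

    Returns ``(meshes, truth, icp_results)`` with meshes in the world
    frame.
    """
    scanner = scanner or ScannerConfig()
    scanner = ScannerConfig.from_dict({**scanner.to_dict(), "seed": seed})
    leaves, truth = generate_canopy(
        n_leaves=n_leaves, height=height, footprint=footprint, seed=seed
    )
    clouds, true_transforms = simulate_scan(leaves, scanner)
    truth.station_transforms = true_transforms
    merged, _pair, icp_results = register_stations(clouds, scanner)
    world = apply_transform(merged, true_transforms[0], frame_id="world")
    meshes, _skipped = reconstruct_leaves(world, meshing, fuse_cell)
    return meshes, truth, icp_results


def leaf_area_trial(seed: int, n_leaves: int = 30) -> float:
    """MAPE (%) of mesh-derived vs true leaf areas for one scanned canopy.

    Leaves reconstructed by the pipeline (the overwhelming majority; a leaf
    can drop out only if occlusion leaves it fewer points than the meshing
    minimum) are scored against their quadrature-oracle areas.
    """
    meshes, truth, _icp = reconstruct_synthetic_scene(seed, n_leaves=n_leaves)
    from .meshing import mesh_area

    est = np.array([mesh_area(m) for m in meshes])
    act = np.array([truth.true_areas[m.leaf_id] for m in meshes])
    return mape(est, act)


def leaf_area_benchmark(seeds) -> dict:
    """Median (and per-seed) leaf-area MAPE over a set of scene seeds."""
    per_seed = {int(s): leaf_area_trial(int(s)) for s in seeds}
    values = np.array(list(per_seed.values()))
    return {
        "median_mape_percent": float(np.median(values)),
        "mean_mape_percent": float(values.mean()),
        "per_seed": per_seed,
        "n_seeds": len(per_seed),
    }


def inclination_trial(
    seed: int,
    n_canopy_leaves: int = 30,
    n_pick: int = 5,
    n_samples: int = 60,
    normal_radius: float = 0.008,
) -> dict:
    """Mean absolute inclination error (degrees) over sampled surface points.

    Reconstructs the standard scanned canopy, picks ``n_pick`` leaves at
    random from the reconstructed ones (as one would pick leaves from the
    meshed canopy in a field campaign), draws ``n_samples`` area-uniform
    points across them (allocated to leaves proportionally to mesh area),
    and compares each point's mesh-derived inclination — zenith angle of
    the barycentrically interpolated, upward-folded vertex normal — with
    the analytic normal's zenith angle at the nearest point of the
    generating parametric surface.
    """
    meshes, truth, _icp = reconstruct_synthetic_scene(seed, n_leaves=n_canopy_leaves)
    from .meshing import mesh_area

    rng = np.random.default_rng(seed)
    pick = rng.choice(len(meshes), size=min(n_pick, len(meshes)), replace=False)
    meshes = [meshes[i] for i in sorted(pick)]
    leaves_by_id = {lf.leaf_id: lf for lf in truth.leaves}
    areas = np.array([mesh_area(m) for m in meshes])
    weights = areas / areas.sum()
    counts = np.floor(weights * n_samples).astype(int)
    # distribute the remainder to the largest leaves, keeping the total fixed
    for i in np.argsort(weights)[::-1]:
        if counts.sum() >= n_samples:
            break
        counts[i] += 1
    errors = []
    for m, k in zip(meshes, counts):
        if k == 0:
            continue
        pts, mesh_angles = sample_inclinations(
            m, k, rng, method="vertex", normal_radius=normal_radius
        )
        lf = leaves_by_id[m.leaf_id]
        # nearest parametric point via a fine surface grid
        u = np.linspace(0.0, 1.0, 400)
        t = np.linspace(-1.0, 1.0, 60)
        uu, tt = np.meshgrid(u, t, indexing="ij")
        grid_pts = lf.surface(uu.ravel(), tt.ravel())
        _d, idx = cKDTree(grid_pts).query(pts)
        true_angles = lf.inclination(uu.ravel()[idx])
        errors.append(np.abs(mesh_angles - true_angles))
    err = np.concatenate(errors)
    return {
        "mean_abs_error_deg": float(err.mean()),
        "max_abs_error_deg": float(err.max()),
        "n_samples": int(len(err)),
        "n_leaves": len(meshes),
    }
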