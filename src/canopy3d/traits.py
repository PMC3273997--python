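"""Canopy descriptors derived from per-leaf surface meshes.

* per-leaf records — one-sided area, height (area-weighted centroid z),
  face count;
* LAD profile — one-sided leaf area per unit volume of each horizontal
  layer (m² m⁻³), layers of fixed thickness (0.20 m by default) stacked
  over [z_min, z_max); LAI is its vertical integral (m² m⁻²);
* inclination statistics — mean/std of the leaf inclination angle over
  points sampled uniformly by area on the leaf surface;
* MAPE — the mean absolute percent error used to validate mesh-derived
  leaf areas against reference measurements.

Faces are assigned to layers by the z of their centroid.  With faces a few
millimeters across and layers tens of centimeters thick, the bias from not
splitting triangles at layer boundaries is below one face height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .meshing import (
    axis_mean,
    face_areas,
    face_inclination_angles,
    mesh_area,
    vertex_normals,
    vertex_normals_radius,
)
from .pointcloud import TriangleMesh

__all__ = [
    "LeafRecord",
    "LADProfile",
    "InclinationStats",
    "leaf_records",
    "lad_profile",
    "lai",
    "sample_surface",
    "inclination_stats",
    "mape",
]


@dataclass
class LeafRecord:
    leaf_id: int
    area: float  # m^2, one-sided
    centroid_z: float  # m, area-weighted face-centroid height
    n_faces: int


@dataclass
class LADProfile:
    """Vertical leaf-area-density profile plus its integral (LAI).

    ``lad[k]`` covers the layer [layer_bottom_z[k], layer_bottom_z[k] +
    layer_thickness).  ``overflow_area`` records leaf area whose face
    centroids fell outside [z_min, z_max] — reported, never silently
    dropped — so the conservation identity

        Σ lad·thickness·footprint_area + overflow_area = Σ mesh areas

    holds exactly.
    """

    layer_bottom_z: np.ndarray
    layer_thickness: float
    footprint_area: float
    lad: np.ndarray
    overflow_area: float = 0.0

    @property
    def lai(self) -> float:
        return float(np.sum(self.lad) * self.layer_thickness)


@dataclass
class InclinationStats:
    leaf_id: int
    sampled_angles: np.ndarray  # degrees, one per sampled surface point
    mean: float
    std_dev: float  # population standard deviation


def leaf_records(meshes) -> list[LeafRecord]:
    """One record per mesh; leaf ids must be unique across the collection."""
    records = []
    seen = set()
    for mesh in meshes:
        if mesh.leaf_id in seen:
            raise ValidationError(f"duplicate leaf_id {mesh.leaf_id}")
        seen.add(mesh.leaf_id)
        areas = face_areas(mesh)
        total = float(areas.sum())
        centroids_z = mesh.vertices[mesh.faces, 2].mean(axis=1)
        cz = float((centroids_z * areas).sum() / total) if total > 0 else float("nan")
        records.append(
            LeafRecord(
                leaf_id=mesh.leaf_id,
                area=total,
                centroid_z=cz,
                n_faces=mesh.n_faces,
            )
        )
    return records


def lad_profile(
    meshes,
    footprint_area: float,
    layer_thickness: float = 0.20,
    z_min: float = 0.0,
    z_max: float | None = None,
) -> LADProfile:
    """Bin leaf area into horizontal layers and divide by layer volume.

    Each face contributes its full area to the layer containing its
    centroid's z; layers are half-open [bottom, top) except the top layer,
    which also includes z == z_max.  ``footprint_area`` is the horizontal
    cross-section of the analyzed region (m²) and must be supplied by the
    caller (or taken from simulator truth).
    """
    if footprint_area <= 0:
        raise ValidationError("footprint_area must be positive")
    if layer_thickness <= 0:
        raise ValidationError("layer_thickness must be positive")
    meshes = list(meshes)
    if z_max is None:
        top = max(
            (float(m.vertices[:, 2].max()) for m in meshes if len(m.vertices)),
            default=z_min + layer_thickness,
        )
        z_max = z_min + layer_thickness * max(
            1, int(np.ceil((top - z_min) / layer_thickness - 1e-12))
        )
    if z_max <= z_min:
        raise ValidationError("z_max must exceed z_min")
    n_layers = max(1, int(np.ceil((z_max - z_min) / layer_thickness - 1e-12)))
    layer_area = np.zeros(n_layers)
    overflow = 0.0
    for mesh in meshes:
        if mesh.n_faces == 0:
            continue
        areas = face_areas(mesh)
        cz = mesh.vertices[mesh.faces, 2].mean(axis=1)
        idx = np.floor((cz - z_min) / layer_thickness).astype(np.int64)
        idx[cz == z_max] = n_layers - 1  # top layer is closed
        inside = (idx >= 0) & (idx < n_layers) & (cz >= z_min) & (cz <= z_max)
        np.add.at(layer_area, idx[inside], areas[inside])
        overflow += float(areas[~inside].sum())
    return LADProfile(
        layer_bottom_z=z_min + layer_thickness * np.arange(n_layers),
        layer_thickness=layer_thickness,
        footprint_area=float(footprint_area),
        lad=layer_area / (footprint_area * layer_thickness),
        overflow_area=overflow,
    )


def lai(profile: LADProfile) -> float:
    """Leaf area index: the vertical integral Σ LAD·thickness (m² m⁻²)."""
    return profile.lai


def sample_surface(mesh: TriangleMesh, n_samples: int, rng):
    """Sample points uniformly by area over the mesh surface.

    Returns ``(points, face_idx, barycentric)`` arrays; reproducible for a
    given ``numpy`` Generator state.
    """
    areas = face_areas(mesh)
    total = areas.sum()
    if mesh.n_faces == 0 or total <= 0:
        raise ValidationError("cannot sample an empty mesh")
    faces = rng.choice(mesh.n_faces, size=n_samples, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n_samples))
    r2 = rng.random(n_samples)
    bary = np.column_stack([1 - r1, r1 * (1 - r2), r1 * r2])
    v = mesh.vertices[mesh.faces[faces]]
    pts = np.einsum("ik,ikj->ij", bary, v)
    return pts, faces, bary


def sample_inclinations(
    mesh: TriangleMesh,
    n_samples: int,
    rng,
    method: str = "face",
    normal_radius: float | None = None,
):
    """Inclination angles (degrees) at area-uniform random surface points.

    ``method="face"`` uses the containing face's normal; ``method="vertex"``
    interpolates the folded vertex normals barycentrically, which smooths
    single-face noise on scan-derived meshes.  With ``normal_radius`` set,
    vertex normals are averaged over every face within that distance
    instead of the 1-ring only (see
    :func:`canopy3d.meshing.vertex_normals_radius`).  Returns
    ``(points, angles)``.
    """
    pts, faces, bary = sample_surface(mesh, n_samples, rng)
    if method == "face":
        angles = face_inclination_angles(mesh)[faces]
    elif method == "vertex":
        if normal_radius is not None:
            normals = vertex_normals_radius(mesh, normal_radius)
            vn = normals[mesh.faces[faces]]  # (n, 3 verts, 3)
            # sign-invariant interpolation: folds through vertical would
            # cancel a plain barycentric average
            n = axis_mean(vn, bary)
        else:
            normals, _ = vertex_normals(mesh)
            vn = normals[mesh.faces[faces]]
            n = np.einsum("ik,ikj->ij", bary, vn)
            n /= np.linalg.norm(n, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(np.abs(n[:, 2]), 0.0, 1.0)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pts, angles


def inclination_stats(
    mesh: TriangleMesh,
    n_samples: int = 20,
    seed: int = 0,
    method: str = "face",
) -> InclinationStats:
    """Mean and population std of inclination over sampled surface points."""
    if n_samples < 1:
        raise ValidationError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    _pts, angles = sample_inclinations(mesh, n_samples, rng, method=method)
    return InclinationStats(
        leaf_id=mesh.leaf_id,
        sampled_angles=angles,
        mean=float(angles.mean()),
        std_dev=float(angles.std()),
    )


def mape(estimated, actual) -> float:
    """Mean absolute percent error: (100/n) Σ |estᵢ − actᵢ| / actᵢ."""
    est = np.asarray(estimated, dtype=np.float64).ravel()
    act = np.asarray(actual, dtype=np.float64).ravel()
    if est.shape != act.shape or est.size == 0:
        raise ValidationError(
            f"estimated and actual must be equal-length and non-empty, "
            f"got {est.shape} vs {act.shape}"
        )
    if np.any(act <= 0):
        raise ValidationError("actual values must be strictly positive")
    return float(100.0 * np.mean(np.abs(est - act) / act))
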