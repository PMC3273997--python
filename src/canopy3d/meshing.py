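"""Per-leaf surface reconstruction and normal/inclination extraction.

A segmented leaf from a high-resolution scan is a near-2.5-D sheet of
points.  It is meshed by fitting the least-squares plane through the points
(principal axes of the centered cloud), projecting onto that plane,
Delaunay-triangulating the 2-D projection and lifting the faces back onto
the original 3-D points — so every vertex of the mesh is a measured point.
The Delaunay triangulation of a projected concave outline necessarily
bridges concavities and holes with long skinny triangles; those are removed
afterwards by dropping any face with an edge longer than ``edge_factor``
times the median nearest-neighbour point spacing.

Leaf inclination at a point is the zenith angle of the surface normal
there: 0° for a horizontal leaf patch, 90° for a vertical one.  Scanned
sheets have no consistent inside/outside, so normals are folded upward
(n_z ≥ 0) before taking the zenith angle, giving angles in [0°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import DegenerateGeometryError, ValidationError
from .pointcloud import PointCloud, TriangleMesh

__all__ = [
    "MeshingParams",
    "fuse_leaf_points",
    "triangulate_leaf",
    "mesh_area",
    "face_areas",
    "face_normals",
    "face_inclination_angles",
    "vertex_normals",
    "point_inclination_angles",
]

_DEGENERATE_AREA = 1e-12  # m^2; faces below this are discarded, not errored


@dataclass
class MeshingParams:
    """Tunables for :func:`triangulate_leaf`.

    edge_factor
        Maximum allowed face edge length, as a multiple of the median
        nearest-neighbour spacing of the leaf's points.  Larger values keep
        more of the convex hull; smaller values carve concavities and holes
        more aggressively (and can only remove area).
    min_points
        Minimum number of points required to attempt meshing.
    """

    edge_factor: float = 3.0
    min_points: int = 10

    def __post_init__(self):
        if not self.edge_factor > 1:
            raise ValidationError("edge_factor must exceed 1")
        if self.min_points < 3:
            raise ValidationError("min_points must be at least 3")


def fuse_leaf_points(points: np.ndarray, cell: float = 0.003) -> np.ndarray:
    """Fuse a multi-station leaf cloud by averaging over a plane-aligned grid.

    The leaf's best-fit plane is gridded into square cells of side ``cell``
    and all points projecting into a cell are replaced by their 3-D
    centroid.  Because the averaging extends without limit along the plane
    normal, this collapses the slightly offset copies of the surface left
    by residual registration error and averages the range noise of
    overlapping stations, while the in-plane resolution stays at ``cell``.
    Recommended before :func:`triangulate_leaf` on merged scans; pointless
    on noise-free single-view data.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if cell <= 0:
        raise ValidationError("cell must be positive")
    if len(pts) == 0:
        return pts
    _centroid, centered, vt = _principal_axes(pts)
    uv = centered @ vt[:2].T
    ij = np.floor(uv / cell).astype(np.int64)
    _uniq, inv, counts = np.unique(ij, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inv, pts)
    fused = sums / counts[:, None]
    first = np.full(len(counts), len(pts), dtype=np.int64)
    np.minimum.at(first, inv, np.arange(len(pts)))
    return fused[np.argsort(first, kind="stable")]


def _principal_axes(points: np.ndarray):
    """Centered principal axes; raises if the cloud is essentially 1-D."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], np.finfo(float).tiny)
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError(
            "leaf points are collinear; no surface can be triangulated"
        )
    return centroid, centered, vt


def triangulate_leaf(
    leaf_points: PointCloud | np.ndarray,
    params: MeshingParams | None = None,
    leaf_id: int | None = None,
) -> TriangleMesh:
    """Triangulate one leaf's point set into a surface mesh.

    Every input point appears as a mesh vertex (some may end up isolated
    after long-edge filtering).  Raises
    :class:`~canopy3d.errors.DegenerateGeometryError` for collinear input
    and :class:`ValueError` when fewer than ``params.min_points`` points are
    supplied.
    """
    params = params or MeshingParams()
    if isinstance(leaf_points, PointCloud):
        pts = leaf_points.points
        if leaf_id is None and leaf_points.labels is not None:
            ids = np.unique(leaf_points.labels)
            if len(ids) != 1:
                raise ValidationError(
                    f"triangulate_leaf expects a single-leaf cloud, "
                    f"got labels {ids.tolist()}"
                )
            leaf_id = int(ids[0])
    else:
        pts = np.asarray(leaf_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < params.min_points:
        raise ValueError(
            f"need at least {params.min_points} points to mesh a leaf, "
            f"got {len(pts)}"
        )
    _centroid, centered, vt = _principal_axes(pts)
    uv = centered @ vt[:2].T  # projection onto the best-fit plane
    tri = Delaunay(uv, qhull_options="Qbb Qc Qz Q12")
    faces = tri.simplices.astype(np.int64)

    # long-edge filter: median NN spacing in 3-D sets the length scale
    nn_dist = cKDTree(pts).query(pts, k=2)[0][:, 1]
    max_edge = params.edge_factor * float(np.median(nn_dist))
    v = pts[faces]
    edge_len = np.stack(
        [
            np.linalg.norm(v[:, 1] - v[:, 0], axis=1),
            np.linalg.norm(v[:, 2] - v[:, 1], axis=1),
            np.linalg.norm(v[:, 0] - v[:, 2], axis=1),
        ],
        axis=1,
    )
    keep = edge_len.max(axis=1) <= max_edge
    # drop numerically degenerate slivers up front
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    keep &= areas > _DEGENERATE_AREA
    return TriangleMesh(pts, faces[keep], leaf_id=1 if leaf_id is None else leaf_id)


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )


def mesh_area(mesh: TriangleMesh) -> float:
    """One-sided surface area: Σ ½‖(v₁−v₀)×(v₂−v₀)‖ over faces (m²)."""
    return float(face_areas(mesh).sum())


def face_normals(mesh: TriangleMesh, folded: bool = True) -> np.ndarray:
    """Unit normal per face, folded upward (n_z ≥ 0) by default.

    Raises :class:`~canopy3d.errors.DegenerateGeometryError` naming the
    first zero-area face, if any.
    """
    v = mesh.vertices[mesh.faces]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1)
    bad = np.flatnonzero(norm <= 2 * _DEGENERATE_AREA)
    if bad.size:
        raise DegenerateGeometryError(f"zero-area face at index {int(bad[0])}")
    n = n / norm[:, None]
    if folded:
        n = np.where(n[:, 2:3] < 0, -n, n)
    return n


def face_inclination_angles(mesh: TriangleMesh) -> np.ndarray:
    """Zenith angle of each face normal, degrees in [0, 90]."""
    nz = np.abs(face_normals(mesh, folded=True)[:, 2])
    return np.degrees(np.arccos(np.clip(nz, -1.0, 1.0)))


def vertex_normals(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted average of adjacent (folded) face normals per vertex.

    Returns ``(normals, has_face)``: rows of ``normals`` are unit vectors
    where ``has_face`` is True and NaN where the vertex has no adjacent
    face (isolated after edge filtering).
    """
    n_faces = face_normals(mesh, folded=True)
    weights = face_areas(mesh)
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], n_faces * weights[:, None])
    norm = np.linalg.norm(acc, axis=1)
    has_face = np.zeros(len(mesh.vertices), dtype=bool)
    has_face[mesh.faces.ravel()] = True
    out = np.full_like(acc, np.nan)
    ok = has_face & (norm > 0)
    out[ok] = acc[ok] / norm[ok, None]
    # antipodal cancellation (near-vertical folds) leaves a zero sum; fall
    # back to the largest adjacent face's normal so ok-vertices stay defined
    cancelled = has_face & (norm == 0)
    if cancelled.any():
        for vi in np.flatnonzero(cancelled):
            adj = np.flatnonzero((mesh.faces == vi).any(axis=1))
            out[vi] = n_faces[adj[np.argmax(weights[adj])]]
    return out, has_face


def axis_mean(normals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Sign-invariant weighted mean direction of unit vectors.

    Scanned leaf sheets have no consistent inside/outside, so normals are
    only defined up to sign; a plain vector average cancels wherever the
    surface folds through vertical.  The dyadic (tensor) average — the
    principal eigenvector of Σ wᵢ nᵢ nᵢᵀ — is invariant to per-vector sign
    flips.  ``normals`` is (..., k, 3) with matching ``weights`` (..., k);
    returns (..., 3) unit vectors with non-negative z.
    """
    M = np.einsum("...k,...ki,...kj->...ij", weights, normals, normals)
    _w, v = np.linalg.eigh(M)
    n = v[..., :, -1]  # eigenvector of the largest eigenvalue
    return np.where(n[..., 2:3] < 0, -n, n)


def vertex_normals_radius(mesh: TriangleMesh, radius: float) -> np.ndarray:
    """Vertex normals estimated from all faces within ``radius`` (meters).

    Area-weighted, sign-invariant (:func:`axis_mean`) average of the
    normals of every face whose centroid lies within ``radius`` of the
    vertex.  On scan-derived meshes a single facet spans only the point
    spacing and its normal is noise-dominated; widening the support to a
    patch still far smaller than the leaf's bending radius trades
    negligible curvature bias for a large noise reduction.  Vertices with
    no face in range get NaN.
    """
    n_faces = face_normals(mesh, folded=True)
    weights = face_areas(mesh)
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    tree = cKDTree(centroids)
    out = np.full_like(mesh.vertices, np.nan)
    neighbors = tree.query_ball_point(mesh.vertices, radius)
    for vi, adj in enumerate(neighbors):
        if not adj:
            continue
        out[vi] = axis_mean(n_faces[adj], weights[adj])
    return out


def point_inclination_angles(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex inclination angle, degrees in [0, 90].

    Vertices with no adjacent face get NaN (missing), never a silent 0.
    """
    normals, has_face = vertex_normals(mesh)
    angles = np.full(len(mesh.vertices), np.nan)
    nz = np.abs(normals[has_face, 2])
    angles[has_face] = np.degrees(np.arccos(np.clip(nz, -1.0, 1.0)))
    return angles
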