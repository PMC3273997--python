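import numpy as np
import pytest
from scipy.spatial import Delaunay

import canopy3d as c3
from canopy3d.errors import DegenerateGeometryError, ValidationError
from canopy3d.meshing import (
    face_areas,
    fuse_leaf_points,
    vertex_normals,
)
from tests.conftest import sample_leaf_grid


def tilted_grid(n=21, spacing=0.002, tilt_deg=30.0):
    """Regular n×n grid on a plane tilted about the x-axis."""
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(n * n)])
    a = np.deg2rad(tilt_deg)
    R = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    return pts @ R.T


class TestTriangulateLeaf:
    def test_unit_square_corners_give_two_triangles(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        mesh = c3.triangulate_leaf(pts, c3.MeshingParams(min_points=3))
        assert mesh.n_faces == 2
        assert c3.mesh_area(mesh) == pytest.approx(1.0)

    @pytest.mark.parametrize("tilt", [0.0, 30.0, 60.0])
    def test_tilted_grid_area_is_analytic(self, tilt):
        pts = tilted_grid(tilt_deg=tilt)
        mesh = c3.triangulate_leaf(pts)
        true = (20 * 0.002) ** 2  # grid span is independent of the tilt
        assert c3.mesh_area(mesh) == pytest.approx(true, rel=1e-9)

    def test_curved_leaf_area_matches_quadrature_oracle(self, curved_leaf):
        pts = sample_leaf_grid(curved_leaf, spacing=0.002)
        mesh = c3.triangulate_leaf(pts)
        assert c3.mesh_area(mesh) == pytest.approx(curved_leaf.true_area, rel=0.01)

    def test_every_input_point_is_a_vertex(self, curved_leaf):
        pts = sample_leaf_grid(curved_leaf, spacing=0.004)
        mesh = c3.triangulate_leaf(pts)
        assert len(mesh.vertices) == len(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            c3.triangulate_leaf(np.random.default_rng(0).normal(size=(5, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.linspace(0, 1, 20), [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            c3.triangulate_leaf(line)

    def test_matches_exhaustive_delaunay_without_edge_filter(self, rng):
        """With filtering effectively off, the face set equals the plain 2-D
        Delaunay of the projected points (checked via the empty-circumcircle
        property on random planar clouds)."""
        uv = rng.uniform(0, 0.1, (40, 2))
        pts = np.column_stack([uv, np.zeros(40)])
        mesh = c3.triangulate_leaf(pts, c3.MeshingParams(edge_factor=1e9, min_points=3))
        oracle = {frozenset(s) for s in Delaunay(uv).simplices}
        got = {frozenset(f) for f in mesh.faces}
        assert got == oracle

    def test_area_monotone_in_edge_factor(self, curved_leaf):
        pts = sample_leaf_grid(curved_leaf, spacing=0.004)
        factors = [1.2, 1.5, 2, 3, 8]
        areas = [
            c3.mesh_area(c3.triangulate_leaf(pts, c3.MeshingParams(edge_factor=f)))
            for f in factors
        ]
        assert all(a1 <= a2 + 1e-15 for a1, a2 in zip(areas, areas[1:]))

    def test_projection_plane_choice_does_not_change_area(self, curved_leaf):
        """A rigidly rotated copy of the leaf (different PCA plane in world
        axes) meshes to the same area."""
        pts = sample_leaf_grid(curved_leaf, spacing=0.003)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [25, 40, 60], degrees=True).as_matrix()
        a1 = c3.mesh_area(c3.triangulate_leaf(pts))
        a2 = c3.mesh_area(c3.triangulate_leaf(pts @ R.T))
        assert a1 == pytest.approx(a2, rel=1e-6)


class TestMeshArea:
    def test_empty_face_list_is_zero(self):
        mesh = c3.TriangleMesh(np.zeros((3, 3)) + np.eye(3), np.empty((0, 3), int))
        assert c3.mesh_area(mesh) == 0.0

    def test_unit_square_exact(self, unit_square_mesh):
        assert c3.mesh_area(unit_square_mesh) == 1.0

    def test_invariant_under_random_rigid_motion(self, rng, unit_square_mesh):
        from scipy.spatial.transform import Rotation

        a0 = c3.mesh_area(unit_square_mesh)
        for _ in range(200):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-10, 10, 3)
            moved = c3.TriangleMesh(
                unit_square_mesh.vertices @ R.T + t, unit_square_mesh.faces
            )
            assert abs(c3.mesh_area(moved) - a0) < 1e-12


class TestNormalsAndInclination:
    def test_horizontal_face_normal_up(self, unit_square_mesh):
        n = c3.face_normals(unit_square_mesh)
        np.testing.assert_allclose(n, [[0, 0, 1], [0, 0, 1]], atol=1e-15)

    def test_vertical_face_normal_horizontal_unit(self):
        mesh = c3.TriangleMesh(
            np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1.0]]), np.array([[0, 1, 2]])
        )
        n = c3.face_normals(mesh)[0]
        assert n[2] == pytest.approx(0.0, abs=1e-15)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)

    def test_random_faces_unit_and_orthogonal(self, rng):
        verts = rng.normal(size=(300, 3))
        faces = np.arange(300).reshape(100, 3)
        mesh = c3.TriangleMesh(verts, faces)
        n = c3.face_normals(mesh, folded=False)
        assert np.abs(np.linalg.norm(n, axis=1) - 1).max() < 1e-12
        e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
        assert np.abs(np.einsum("ij,ij->i", n, e1)).max() < 1e-9

    def test_zero_area_face_error_names_face(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        mesh = c3.TriangleMesh(verts, np.array([[0, 1, 3], [0, 1, 2]]))
        with pytest.raises(DegenerateGeometryError, match="index 1"):
            c3.face_normals(mesh)

    @pytest.mark.parametrize("theta", [0, 15, 30, 45, 60, 75, 90])
    def test_planar_leaf_at_tilt_theta_returns_theta(self, theta):
        pts = tilted_grid(n=11, spacing=0.01, tilt_deg=theta)
        mesh = c3.triangulate_leaf(pts)
        angles = c3.point_inclination_angles(mesh)
        ok = ~np.isnan(angles)
        assert ok.any()
        np.testing.assert_allclose(angles[ok], theta, atol=1e-9)

    def test_curved_leaf_vertex_angles_match_analytic(self, curved_leaf):
        """Interior vertex inclinations within 2° of the closed-form
        normal zenith angles of the generating surface."""
        from scipy.spatial import cKDTree

        pts = sample_leaf_grid(curved_leaf, spacing=0.002)
        mesh = c3.triangulate_leaf(pts)
        angles = c3.point_inclination_angles(mesh)
        u = np.linspace(0, 1, 500)
        t = np.linspace(-1, 1, 80)
        uu, tt = np.meshgrid(u, t, indexing="ij")
        grid = curved_leaf.surface(uu.ravel(), tt.ravel())
        d, idx = cKDTree(grid).query(mesh.vertices)
        true = curved_leaf.inclination(uu.ravel()[idx])
        # interior = vertices well inside the planform boundary
        interior = np.abs(tt.ravel()[idx]) < 0.8
        ok = interior & ~np.isnan(angles)
        assert np.abs(angles[ok] - true[ok]).max() < 2.0

    def test_isolated_vertices_flagged_nan_not_zero(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5.0]])
        mesh = c3.TriangleMesh(verts, np.array([[0, 1, 2]]))
        angles = c3.point_inclination_angles(mesh)
        assert np.isnan(angles[3]) and not np.isnan(angles[:3]).any()

    def test_angles_always_within_0_90(self, rng):
        verts = rng.normal(size=(90, 3))
        mesh = c3.TriangleMesh(verts, np.arange(90).reshape(30, 3))
        _n, has = vertex_normals(mesh)
        angles = c3.point_inclination_angles(mesh)
        assert np.all((angles[has] >= 0) & (angles[has] <= 90))


class TestFuseLeafPoints:
    def test_collapses_duplicate_sheets(self, rng):
        base = tilted_grid(n=15, spacing=0.003, tilt_deg=20)
        normal = np.array([0, -np.sin(np.deg2rad(20)), np.cos(np.deg2rad(20))])
        doubled = np.vstack([base + 0.002 * normal, base - 0.002 * normal])
        fused = fuse_leaf_points(doubled, cell=0.003)
        assert len(fused) == len(base)
        # the mid-surface is recovered
        d = np.linalg.norm(fused[:, None] - base[None], axis=2).min(axis=1)
        assert d.max() < 1e-9

    def test_noise_suppression_improves_area(self, rng, curved_leaf):
        pts = sample_leaf_grid(curved_leaf, spacing=0.002)
        noisy = np.vstack([pts + rng.normal(0, 5e-4, pts.shape) for _ in range(3)])
        raw = c3.mesh_area(c3.triangulate_leaf(noisy))
        fused = c3.mesh_area(c3.triangulate_leaf(fuse_leaf_points(noisy, 0.003)))
        true = curved_leaf.true_area
        assert abs(fused - true) < abs(raw - true)
        assert fused == pytest.approx(true, rel=0.05)
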