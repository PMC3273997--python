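import numpy as np
import pytest
from scipy.spatial import cKDTree

import canopy3d as c3
from canopy3d.errors import ValidationError
from canopy3d.simulate import _scan_station_grid


def flat_leaf(leaf_id=1, base=(0, 0, 1.0), incl=0.0, az=0.0, L=0.3, W=0.3):
    return c3.ParametricLeaf(leaf_id, np.asarray(base, float), az, incl, L, W, 0.0)


def beam_grid(config):
    """All beam directions of one station, replicating the scan grid."""
    step = config.angular_step_rad
    zen_lo, zen_hi = np.deg2rad(config.zenith_span_deg)
    zen = zen_lo + step * np.arange(int((zen_hi - zen_lo) / step) + 1)
    half = np.deg2rad(config.azimuth_span_deg) / 2
    az = -half + step * np.arange(int(2 * half / step) + 1)
    zz, aa = np.meshgrid(zen, az, indexing="ij")
    sz = np.sin(zz)
    return np.stack([sz * np.cos(aa), sz * np.sin(aa), np.cos(zz)], axis=-1).reshape(
        -1, 3
    )


class TestParametricLeaf:
    def test_flat_ellipse_area_closed_form(self):
        lf = c3.ParametricLeaf(1, np.zeros(3), 0, 0, 0.2, 0.1, 0.0)
        assert lf.true_area == pytest.approx(np.pi * 0.1 * 0.05, rel=1e-4)

    def test_curvature_only_adds_area(self, rng):
        for _ in range(10):
            L = rng.uniform(0.05, 0.25)
            W = L * rng.uniform(0.3, 0.6)
            flat = c3.ParametricLeaf(1, np.zeros(3), 0, 0, L, W, 0.0)
            bent = c3.ParametricLeaf(1, np.zeros(3), 0, 0, L, W, 0.1 * L)
            assert bent.true_area >= flat.true_area

    def test_normals_unit_and_match_finite_differences(self, curved_leaf):
        u = np.linspace(0.05, 0.95, 30)
        t = np.full_like(u, 0.3)
        n = curved_leaf.normal(u, t)
        assert np.abs(np.linalg.norm(n, axis=1) - 1).max() < 1e-12
        h = 1e-6
        du = (curved_leaf.surface(u + h, t) - curved_leaf.surface(u - h, t)) / (2 * h)
        dt = (curved_leaf.surface(u, t + h) - curved_leaf.surface(u, t - h)) / (2 * h)
        assert np.abs(np.einsum("ij,ij->i", n, du)).max() < 1e-4
        assert np.abs(np.einsum("ij,ij->i", n, dt)).max() < 1e-6

    def test_tessellation_vertices_lie_on_surface(self, curved_leaf):
        verts, faces = curved_leaf.tessellate(0.004)
        _pts, _areas, _n = curved_leaf.quadrature(400, 400)
        d, _ = cKDTree(_pts).query(verts)
        assert d.max() < 1e-3
        assert faces.max() < len(verts)


class TestGenerateCanopy:
    def test_same_seed_identical_scene(self):
        l1, t1 = c3.generate_canopy(n_leaves=5, seed=11)
        l2, t2 = c3.generate_canopy(n_leaves=5, seed=11)
        for a, b in zip(l1, l2):
            np.testing.assert_array_equal(a.base, b.base)
            assert a.length == b.length and a.azimuth_deg == b.azimuth_deg
        assert t1.true_areas == t2.true_areas

    def test_truth_conservation_invariant(self):
        _leaves, truth = c3.generate_canopy(n_leaves=10, seed=2)
        total = sum(truth.true_areas.values())
        assert truth.lai * truth.footprint_area == pytest.approx(total, rel=1e-9)

    def test_dimensions_validated(self):
        with pytest.raises(ValidationError):
            c3.generate_canopy(n_leaves=0)
        with pytest.raises(ValidationError):
            c3.generate_canopy(n_leaves=1, footprint=(0, 1))


class TestRayTriangleIntersect:
    TRI = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])

    def test_straight_down_hit_at_distance_one(self):
        t = c3.ray_triangle_intersect([0.25, 0.25, 1.0], [0, 0, -1.0], self.TRI)
        assert t == pytest.approx(1.0)

    def test_parallel_ray_misses(self):
        assert c3.ray_triangle_intersect([0, 0, 1.0], [1, 0, 0.0], self.TRI) is None

    def test_shared_edge_cannot_be_missed(self):
        """A ray through an edge shared by two faces hits at least one of
        them (boundary-inclusive), at the same distance when it hits both."""
        other = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        origin, direction = [0.5, 0.5, 1.0], [0, 0, -1.0]  # through shared edge
        hits = [
            c3.ray_triangle_intersect(origin, direction, tri)
            for tri in (self.TRI, other)
        ]
        hits = [h for h in hits if h is not None]
        assert len(hits) >= 1
        assert all(h == pytest.approx(1.0) for h in hits)

    def test_agrees_with_barycentric_oracle(self, rng):
        """Dual-route check against an independent plane-intersection +
        barycentric-coordinate solver on random ray/triangle pairs."""

        def oracle(o, d, tri):
            v0, v1, v2 = tri
            n = np.cross(v1 - v0, v2 - v0)
            denom = n @ d
            if abs(denom) < 1e-14:
                return None
            t = (n @ (v0 - o)) / denom
            if t <= 1e-9:
                return None
            p = o + t * d
            # barycentric via normal-projected areas
            area = n @ n
            w0 = n @ np.cross(v1 - p, v2 - p) / area
            w1 = n @ np.cross(v2 - p, v0 - p) / area
            w2 = 1.0 - w0 - w1
            eps = 1e-9
            if w0 < -eps or w1 < -eps or w2 < -eps:
                return None
            return t

        mismatches = 0
        for _ in range(3000):
            o = rng.uniform(-1, 1, 3)
            d = rng.normal(size=3)
            tri = rng.uniform(-1, 1, (3, 3))
            a = c3.ray_triangle_intersect(o, d, tri)
            b = oracle(o, d, tri)
            if (a is None) != (b is None):
                mismatches += 1  # boundary-grazing disagreement only
            elif a is not None:
                assert a == pytest.approx(b, rel=1e-9)
        assert mismatches <= 1

    def test_zero_direction_rejected(self):
        with pytest.raises(ValidationError):
            c3.ray_triangle_intersect([0, 0, 0], [0, 0, 0], self.TRI)


class TestSimulateScan:
    def test_deterministic_for_fixed_seed(self):
        leaves, _ = c3.generate_canopy(n_leaves=3, seed=5)
        cfg = c3.ScannerConfig(seed=5, azimuth_span_deg=4.0)
        c1, t1 = c3.simulate_scan(leaves, cfg)
        c2, t2 = c3.simulate_scan(leaves, cfg)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.points, b.points)
            np.testing.assert_array_equal(a.labels, b.labels)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.rotation, b.rotation)

    def test_zero_noise_points_lie_on_flat_leaf(self):
        leaf = flat_leaf(base=(-0.15, -0.15, 1.0))
        cfg = c3.ScannerConfig(
            n_stations=1,
            station_azimuths_deg=(0.0,),
            range_noise_sd=0.0,
            azimuth_jitter_deg=0.0,
            range_jitter_m=0.0,
            height_jitter_m=0.0,
            seed=0,
        )
        clouds, transforms = c3.simulate_scan([leaf], cfg)
        world = transforms[0].apply(clouds[0].points)
        assert len(world) > 100
        np.testing.assert_allclose(world[:, 2], 1.0, atol=1e-9)
        assert set(clouds[0].labels) == {1}

    def test_occlusion_lower_leaf_gets_fewer_returns(self):
        # scan steeply from above-side so the upper leaf shadows the lower
        upper = flat_leaf(leaf_id=1, base=(-0.15, -0.15, 1.0))
        lower = flat_leaf(leaf_id=2, base=(-0.15, -0.15, 0.9))
        cfg = c3.ScannerConfig(
            n_stations=1,
            station_azimuths_deg=(0.0,),
            range_m=2.0,
            height_m=2.5,
            zenith_span_deg=(120.0, 150.0),
            azimuth_span_deg=20.0,
            range_noise_sd=0.0,
            azimuth_jitter_deg=0.0,
            range_jitter_m=0.0,
            height_jitter_m=0.0,
            seed=0,
        )
        (cloud,), _t = c3.simulate_scan([upper, lower], cfg)
        n_upper = int((cloud.labels == 1).sum())
        n_lower = int((cloud.labels == 2).sum())
        assert n_lower < n_upper

    def test_grid_scan_matches_exhaustive_ray_oracle(self):
        """Nearest-hit grid rasterization equals brute-force casting of
        every beam against every triangle (small scene, ≤ 60 triangles)."""
        leaves = [
            flat_leaf(leaf_id=1, base=(-0.1, -0.1, 1.25), L=0.2, W=0.2),
            flat_leaf(leaf_id=2, base=(-0.1, -0.1, 1.1), incl=25.0, L=0.2, W=0.2),
        ]
        cfg = c3.ScannerConfig(
            n_stations=1,
            station_azimuths_deg=(0.0,),
            azimuth_span_deg=1.2,
            angular_step_rad=2e-3,
            truth_edge_m=0.08,
            range_noise_sd=0.0,
            azimuth_jitter_deg=0.0,
            range_jitter_m=0.0,
            height_jitter_m=0.0,
            seed=0,
        )
        tris, labels = [], []
        for lf in leaves:
            v, f = lf.tessellate(cfg.truth_edge_m)
            tris.append(v[f])
            labels.append(np.full(len(f), lf.leaf_id))
        tris = np.vstack(tris)
        labels = np.concatenate(labels)
        assert len(tris) <= 60
        T = c3.station_transform(0.0, cfg.range_m, cfg.height_m)
        inv = T.inverse()
        tris_s = tris.reshape(-1, 3) @ inv.rotation.T + inv.translation
        tris_s = tris_s.reshape(-1, 3, 3)

        tval, dirs, leaf = _scan_station_grid(tris_s, labels, cfg)
        got = {}
        for tv, d, l in zip(tval, dirs, leaf):
            got[tuple(np.round(d, 12))] = (tv, l)

        expect = {}
        for d in beam_grid(cfg):
            best = None
            for tri, l in zip(tris_s, labels):
                t = c3.ray_triangle_intersect(np.zeros(3), d, tri)
                if t is not None and (best is None or t < best[0]):
                    best = (t, l)
            if best is not None:
                expect[tuple(np.round(d, 12))] = best
        assert set(got) == set(expect)
        for k in got:
            assert got[k][0] == pytest.approx(expect[k][0], abs=1e-9)
            assert got[k][1] == expect[k][1]

    def test_point_spacing_matches_2mm_on_frontoparallel_plane(self):
        # vertical leaf facing station 1 at scanner height
        leaf = c3.ParametricLeaf(
            1, np.array([0.0, 0.0, 1.45]), 0.0, 90.0, 0.3, 0.3, 0.0
        )
        cfg = c3.ScannerConfig(
            n_stations=1,
            station_azimuths_deg=(0.0,),
            range_noise_sd=0.0,
            azimuth_jitter_deg=0.0,
            range_jitter_m=0.0,
            height_jitter_m=0.0,
            seed=0,
        )
        (cloud,), _ = c3.simulate_scan([leaf], cfg)
        assert len(cloud) > 1000
        d, _ = cKDTree(cloud.points).query(cloud.points, k=2)
        spacing = np.median(d[:, 1])
        assert spacing == pytest.approx(0.002, rel=0.2)

    def test_true_transforms_place_points_on_surfaces(self, small_scene):
        """Merging via the true station transforms leaves every point
        within ~3σ of its leaf's surface."""
        truth = small_scene["truth"]
        clouds = small_scene["clouds"]
        transforms = small_scene["transforms"]
        quad = {
            lf.leaf_id: cKDTree(lf.quadrature(300, 60)[0]) for lf in truth.leaves
        }
        sigma = small_scene["config"].range_noise_sd
        for cloud, T in zip(clouds, transforms):
            world = T.apply(cloud.points)
            for leaf_id in np.unique(cloud.labels):
                d, _ = quad[leaf_id].query(world[cloud.labels == leaf_id])
                # quadrature-grid resolution adds ~1 mm to the noise bound
                assert np.percentile(d, 99) < 3 * sigma + 1.5e-3
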