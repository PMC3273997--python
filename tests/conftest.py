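import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import canopy3d as c3

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square_mesh():
    """Two triangles tiling the unit square in the z=0 plane."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return c3.TriangleMesh(verts, faces, leaf_id=1)


@pytest.fixture
def curved_leaf():
    """A curved parametric leaf with closed-form normals and area oracle."""
    return c3.ParametricLeaf(
        leaf_id=1,
        base=np.array([0.0, 0.0, 1.0]),
        azimuth_deg=30.0,
        inclination_deg=40.0,
        length=0.15,
        width=0.07,
        curvature=0.02,
    )


def sample_leaf_grid(leaf, spacing=0.002):
    """Points sampled directly on the parametric surface at ~spacing."""
    n_u = int(np.ceil(leaf.length / spacing)) + 1
    n_t = int(np.ceil(leaf.width / spacing)) + 1
    u = np.linspace(0.0, 1.0, n_u)
    t = np.linspace(-1.0, 1.0, n_t)
    uu, tt = np.meshgrid(u, t, indexing="ij")
    pts = leaf.surface(uu.ravel(), tt.ravel())
    return np.unique(np.round(pts, 12), axis=0)  # tips collapse to one point


@pytest.fixture(scope="session")
def small_scene():
    """A small simulated 3-station scan shared across integration tests."""
    leaves, truth = c3.generate_canopy(n_leaves=14, seed=7)
    config = c3.ScannerConfig(seed=7)
    clouds, transforms = c3.simulate_scan(leaves, config)
    truth.station_transforms = transforms
    return {
        "leaves": leaves,
        "truth": truth,
        "config": config,
        "clouds": clouds,
        "transforms": transforms,
    }
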