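"""Rigid co-registration of multi-station scans by point-to-point ICP.

A scanner placed at several positions around a canopy produces one cloud
per station, each in the instrument's own frame.  Registration brings them
into a common frame by alternating nearest-neighbour correspondence search
with the closed-form least-squares rigid fit (Kabsch/Horn, via SVD of the
cross-covariance matrix) until the correspondence RMSD stops improving.

The implementation is the classic point-to-point formulation.  Because the
stations only partially overlap (each sees a different side of the canopy,
with occlusion), correspondences are filtered twice per iteration: pairs
farther apart than ``max_distance`` are dropped, and of the survivors any
pair beyond ``trim_factor`` times the median pair distance is trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EstimationError, ValidationError
from .pointcloud import PointCloud

__all__ = [
    "RigidTransform",
    "ICPResult",
    "estimate_rigid_transform",
    "nearest_correspondences",
    "icp_register",
    "apply_transform",
    "azimuth_init",
]

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion p ↦ R·p + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation has determinant -1 (reflection)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=np.float64).reshape(3, 3),
            np.asarray(d["translation"], dtype=np.float64),
        )


@dataclass
class ICPResult:
    """Outcome of an ICP run.

    ``rmsd`` is the root-mean-square distance over the correspondences
    accepted in the final iteration; ``rmsd_history`` records it per
    iteration.
    """

    transform: RigidTransform
    rmsd: float
    iterations: int
    converged: bool
    n_correspondences: int = 0
    rmsd_history: list = field(default_factory=list)


def azimuth_init(delta_azimuth_deg: float, pivot=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Initial guess for registering two stations from the scan geometry.

    Stations set out around a canopy at nominal azimuths differ, to first
    order, by a rotation about the canopy's vertical axis.  In the target
    station's frame that axis passes through ``pivot`` (for a scanner aimed
    along +x at a canopy ``range`` meters away, ``pivot=(range, 0, 0)``).
    ``delta_azimuth_deg`` is the source station's azimuth minus the
    target's.
    """
    a = np.deg2rad(delta_azimuth_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    q = np.asarray(pivot, dtype=np.float64).reshape(3)
    return RigidTransform(R, q - R @ q)


def estimate_rigid_transform(
    source_points: np.ndarray, target_points: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping paired source onto target points.

    Closed-form Kabsch/Horn solution: SVD of the cross-covariance of the
    centered point sets, with the reflection case corrected so the result is
    always a proper rotation.  Minimizes Σ‖R·sᵢ + t − gᵢ‖².
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise EstimationError(
            f"paired point sets differ in length: {src.shape} vs {tgt.shape}"
        )
    if len(src) < 3:
        raise EstimationError(f"need at least 3 pairs, got {len(src)}")
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, S, Vt = np.linalg.svd(H)
    # collinear sources leave the rotation about their axis unconstrained
    spread = np.linalg.svd(src - cs, compute_uv=False)
    if spread[1] <= 1e-9 * max(spread[0], 1.0):
        raise EstimationError(
            "degenerate correspondence set (points are collinear)"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def nearest_correspondences(
    source: PointCloud | np.ndarray,
    target: PointCloud | np.ndarray,
    max_distance: float = np.inf,
):
    """Nearest-neighbour pairing of each source point with a target point.

    Returns ``(source_idx, target_idx, distances)`` with pairs farther apart
    than ``max_distance`` excluded.
    """
    src = source.points if isinstance(source, PointCloud) else np.asarray(source)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target)
    if len(tgt) == 0:
        raise EstimationError("target cloud is empty")
    dist, idx = cKDTree(tgt).query(src.reshape(-1, 3))
    keep = np.flatnonzero(dist <= max_distance)
    return keep, idx[keep], dist[keep]


def icp_register(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    tolerance: float = 1e-6,
    max_distance: float = 0.05,
    trim_factor: float = 3.0,
    max_points: int = 20000,
) -> ICPResult:
    """Register ``source`` onto ``target`` by point-to-point ICP.

    Parameters
    ----------
    init
        Starting transform (source frame → target frame).  For scans taken
        from surveyed positions use :func:`azimuth_init`; identity works
        only when the clouds already roughly coincide.
    max_iterations, tolerance
        Stop after ``max_iterations`` or once the iteration-to-iteration
        RMSD improvement drops below ``tolerance`` (meters).
    max_distance
        Correspondences farther apart than this are treated as non-overlap
        and dropped each iteration (meters).
    trim_factor
        Additional trimming: of the accepted pairs, those beyond
        ``trim_factor`` × the median pair distance are discarded.
    max_points
        Source points are strided down to at most this many for the
        correspondence search (deterministic subsampling); the returned
        transform applies to the full cloud.

    Returns the composed transform mapping the source frame into the target
    frame, with the final correspondence RMSD.
    """
    if len(source) < 3 or len(target) < 3:
        raise EstimationError("both clouds need at least 3 points")
    T = RigidTransform.identity() if init is None else init
    src_all = source.points
    stride = max(1, int(np.ceil(len(src_all) / max_points)))
    src = src_all[::stride]
    tree = cKDTree(target.points)

    rmsd_prev = np.inf
    history: list[float] = []
    converged = False
    n_pairs = 0
    it = 0
    for it in range(1, max_iterations + 1):
        moved = T.apply(src)
        dist, idx = tree.query(moved)
        keep = dist <= max_distance
        if keep.sum() >= 3:
            med = np.median(dist[keep])
            keep &= dist <= trim_factor * max(med, np.finfo(float).tiny)
        if keep.sum() < 3:
            raise EstimationError(
                "ICP correspondence set collapsed below 3 pairs; increase "
                "max_distance or provide a better initial transform"
            )
        pairs_src = src[keep]
        pairs_tgt = target.points[idx[keep]]
        # refit directly from original source coordinates: the result is the
        # full composed transform, avoiding drift from incremental updates
        T = estimate_rigid_transform(pairs_src, pairs_tgt)
        resid = T.apply(pairs_src) - pairs_tgt
        rmsd = float(np.sqrt(np.mean(np.einsum("ij,ij->i", resid, resid))))
        history.append(rmsd)
        n_pairs = int(keep.sum())
        if rmsd_prev - rmsd < tolerance:
            converged = True
            break
        rmsd_prev = rmsd
    return ICPResult(
        transform=T,
        rmsd=history[-1],
        iterations=it,
        converged=converged,
        n_correspondences=n_pairs,
        rmsd_history=history,
    )


def apply_transform(
    cloud: PointCloud, transform: RigidTransform, frame_id: str | None = None
) -> PointCloud:
    """Map every point p ↦ R·p + t, preserving labels.

    ``frame_id`` names the destination frame; when omitted the old name is
    suffixed to record that the cloud left its original frame.
    """
    new_frame = frame_id if frame_id is not None else f"{cloud.frame_id}:transformed"
    labels = None if cloud.labels is None else cloud.labels.copy()
    return PointCloud(transform.apply(cloud.points), labels, new_frame)
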