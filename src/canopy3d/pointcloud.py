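"""Core geometric containers and ASCII point-cloud / mesh I/O.

All coordinates are in meters, in a right-handed frame with z pointing up
(the zenith axis); leaf inclination and LAD layering elsewhere in the
package rely on that convention.

Supported on-disk dialects (all plain text, human-inspectable):

* point clouds — ASCII PLY 1.0 (vertex properties ``x y z`` and optional
  integer ``leaf_id``), XYZ (``x y z`` per line, whitespace separated) and
  CSV (``x,y,z[,leaf_id]`` with a header row);
* triangle meshes — ASCII PLY (vertex + face elements) and OBJ (``v``/``f``
  records only; OBJ face indices are 1-based on disk, 0-based in memory).

Leaf label 0 is reserved for "unassigned / not a leaf"; real leaves are
numbered from 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "read_point_cloud",
    "write_point_cloud",
    "read_mesh",
    "write_mesh",
    "merge_clouds",
    "voxel_downsample",
]

_FLOAT_FMT = "%.10g"


@dataclass
class PointCloud:
    """Labeled 3-D points from one scan station or a merged scene.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of x, y, z in meters.
    labels
        Optional ``(n,)`` integer leaf identifiers; 0 means unassigned.
    frame_id
        Name of the coordinate frame the points live in, e.g. ``"station1"``
        or ``"world"``.
    """

    points: np.ndarray
    labels: np.ndarray | None = None
    frame_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(
                f"points must have shape (n, 3), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            bad = int(np.flatnonzero(~np.isfinite(pts).all(axis=1))[0])
            raise ValidationError(f"non-finite coordinate at point {bad}")
        self.points = pts
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=np.int64)
            if lab.shape != (len(pts),):
                raise ValidationError(
                    f"labels length {lab.shape} does not match "
                    f"{len(pts)} points"
                )
            if lab.size and lab.min() < 0:
                raise ValidationError("leaf labels must be non-negative")
            self.labels = lab

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_idx) -> "PointCloud":
        """Sub-cloud at the given boolean mask or index array."""
        lab = None if self.labels is None else self.labels[mask_or_idx]
        return PointCloud(self.points[mask_or_idx], lab, self.frame_id)

    def leaf_ids(self) -> np.ndarray:
        """Sorted unique leaf labels present, excluding the 0 reserve."""
        if self.labels is None:
            return np.empty(0, dtype=np.int64)
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class TriangleMesh:
    """Triangulated leaf surface: vertices in meters + face index triples."""

    vertices: np.ndarray
    faces: np.ndarray
    leaf_id: int = 1

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.size == 0:
            v = v.reshape(0, 3)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(
                f"vertices must have shape (n, 3), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite vertex coordinate")
        f = np.asarray(self.faces, dtype=np.int64)
        if f.size == 0:
            f = f.reshape(0, 3)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError(f"faces must have shape (m, 3), got {f.shape}")
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise ValidationError(
                    f"face index out of range [0, {len(v)}): "
                    f"min {f.min()}, max {f.max()}"
                )
            if np.any(
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            ):
                raise ValidationError("face with repeated vertex index")
        self.vertices = v
        self.faces = f
        self.leaf_id = int(self.leaf_id)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


# ---------------------------------------------------------------------------
# point-cloud I/O


def _infer_format(path: Path, fmt: str | None, allowed: tuple[str, ...]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in allowed:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {allowed}")
    return fmt


def read_point_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from an ASCII PLY, XYZ, or CSV file.

    An integer ``leaf_id`` column/property, when present, is read into
    :attr:`PointCloud.labels`.
    """
    path = Path(path)
    fmt = _infer_format(path, format, ("ply", "xyz", "csv"))
    if fmt == "ply":
        return _read_ply_cloud(path)
    if fmt == "xyz":
        return _read_xyz(path)
    return _read_csv_cloud(path)


def write_point_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write a cloud in the dialect matching ``format`` (or the file suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format, ("ply", "xyz", "csv"))
    if fmt == "ply":
        _write_ply_cloud(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        _write_csv_cloud(cloud, path)


def _read_xyz(path: Path) -> PointCloud:
    pts = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise ParseError(
                    f"expected 3 coordinates, got {len(parts)}", path, ln
                )
            try:
                pts.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise ParseError(str(exc), path, ln) from exc
    return PointCloud(np.asarray(pts, dtype=np.float64).reshape(-1, 3))


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    np.savetxt(path, cloud.points, fmt=_FLOAT_FMT)


def _read_csv_cloud(path: Path) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(str(exc), path) from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for c in ("x", "y", "z"):
        if c not in cols:
            raise ParseError(f"missing column {c!r} (have {cols})", path, 1)
    pts = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    labels = None
    if "leaf_id" in cols:
        labels = df["leaf_id"].to_numpy(dtype=np.int64)
    return PointCloud(pts, labels)


def _write_csv_cloud(cloud: PointCloud, path: Path) -> None:
    data = {"x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2]}
    if cloud.labels is not None:
        data["leaf_id"] = cloud.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- minimal ASCII PLY codec ------------------------------------------------
# The dialect is deliberately narrow: ASCII PLY 1.0 with a vertex element
# (x, y, z float properties, optional int leaf_id) and an optional face
# element with a vertex_indices list property.


def _parse_ply_header(fh, path):
    line = fh.readline()
    ln = 1
    if line.strip() != "ply":
        raise ParseError("not a PLY file (missing 'ply' magic)", path, ln)
    elements = []  # (name, count, [property names])
    comments = {}
    while True:
        line = fh.readline()
        ln += 1
        if not line:
            raise ParseError("unexpected EOF in header", path, ln)
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ParseError(f"unsupported PLY format {tok[1]!r}", path, ln)
        elif tok[0] == "comment":
            if len(tok) == 3:
                comments[tok[1]] = tok[2]
        elif tok[0] == "element":
            elements.append([tok[1], int(tok[2]), []])
        elif tok[0] == "property":
            if not elements:
                raise ParseError("property before any element", path, ln)
            elements[-1][2].append(tok[-1])
        elif tok[0] == "end_header":
            return elements, comments, ln
        # any other keyword (obj_info ...) is ignored


def _read_ply_cloud(path: Path) -> PointCloud:
    with open(path) as fh:
        elements, _comments, ln = _parse_ply_header(fh, path)
        vert = next((e for e in elements if e[0] == "vertex"), None)
        if vert is None:
            raise ParseError("no vertex element", path, ln)
        props = vert[2]
        try:
            ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
        except ValueError as exc:
            raise ParseError(f"vertex element lacks x/y/z ({props})", path, ln) from exc
        il = props.index("leaf_id") if "leaf_id" in props else None
        n = vert[1]
        pts = np.empty((n, 3))
        labels = np.empty(n, dtype=np.int64) if il is not None else None
        for i in range(n):
            ln += 1
            parts = fh.readline().split()
            if len(parts) < len(props):
                raise ParseError(
                    f"expected {len(props)} values, got {len(parts)}", path, ln
                )
            try:
                pts[i] = float(parts[ix]), float(parts[iy]), float(parts[iz])
                if labels is not None:
                    labels[i] = int(float(parts[il]))
            except ValueError as exc:
                raise ParseError(str(exc), path, ln) from exc
    return PointCloud(pts, labels)


def _write_ply_cloud(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if cloud.labels is not None:
            fh.write("property int leaf_id\n")
        fh.write("end_header\n")
        buf = io.StringIO()
        if cloud.labels is not None:
            for (x, y, z), l in zip(cloud.points, cloud.labels):
                buf.write(
                    f"{x:.10g} {y:.10g} {z:.10g} {int(l)}\n"
                )
        else:
            np.savetxt(buf, cloud.points, fmt=_FLOAT_FMT)
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# mesh I/O


def read_mesh(path, format: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from ASCII PLY or OBJ."""
    path = Path(path)
    fmt = _infer_format(path, format, ("ply", "obj"))
    return _read_ply_mesh(path) if fmt == "ply" else _read_obj(path)


def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a triangle mesh as ASCII PLY or OBJ (1-based face indices)."""
    path = Path(path)
    fmt = _infer_format(path, format, ("ply", "obj"))
    if fmt == "ply":
        _write_ply_mesh(mesh, path)
    else:
        _write_obj(mesh, path)


def _read_ply_mesh(path: Path) -> TriangleMesh:
    with open(path) as fh:
        elements, comments, ln = _parse_ply_header(fh, path)
        leaf_id = int(comments.get("leaf_id", 1))
        vert = next((e for e in elements if e[0] == "vertex"), None)
        if vert is None:
            raise ParseError("no vertex element", path, ln)
        verts = np.empty((vert[1], 3))
        faces: list[list[int]] = []
        for name, count, _props in elements:
            if name == "vertex":
                for i in range(count):
                    ln += 1
                    parts = fh.readline().split()
                    try:
                        verts[i] = [float(p) for p in parts[:3]]
                    except (ValueError, IndexError) as exc:
                        raise ParseError(str(exc), path, ln) from exc
            elif name == "face":
                for _ in range(count):
                    ln += 1
                    parts = fh.readline().split()
                    try:
                        k = int(parts[0])
                        idx = [int(p) for p in parts[1 : 1 + k]]
                    except (ValueError, IndexError) as exc:
                        raise ParseError(str(exc), path, ln) from exc
                    if k != 3:
                        raise ParseError(
                            f"only triangular faces supported, got {k}-gon",
                            path,
                            ln,
                        )
                    faces.append(idx)
            else:  # skip rows of unknown elements
                for _ in range(count):
                    fh.readline()
                    ln += 1
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3), leaf_id)


def _write_ply_mesh(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment leaf_id {mesh.leaf_id}\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        buf = io.StringIO()
        np.savetxt(buf, mesh.vertices, fmt=_FLOAT_FMT)
        for a, b, c in mesh.faces:
            buf.write(f"3 {a} {b} {c}\n")
        fh.write(buf.getvalue())


def _read_obj(path: Path) -> TriangleMesh:
    verts = []
    faces = []
    leaf_id = 1
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "#":
                if len(tok) == 3 and tok[1] == "leaf_id":
                    leaf_id = int(tok[2])
            elif tok[0] == "v":
                try:
                    verts.append([float(t) for t in tok[1:4]])
                except ValueError as exc:
                    raise ParseError(str(exc), path, ln) from exc
            elif tok[0] == "f":
                try:
                    # tolerate v/vt/vn references; only the vertex index is used
                    idx = [int(t.split("/")[0]) for t in tok[1:]]
                except ValueError as exc:
                    raise ParseError(str(exc), path, ln) from exc
                if len(idx) != 3:
                    raise ParseError(
                        f"only triangular faces supported, got {len(idx)}-gon",
                        path,
                        ln,
                    )
                if any(i == 0 for i in idx):
                    raise ParseError("OBJ face indices are 1-based", path, ln)
                # negative OBJ indices count back from the current vertex list
                faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
    return TriangleMesh(
        np.asarray(verts, dtype=np.float64).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        leaf_id,
    )


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# leaf_id {mesh.leaf_id}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.10g} {y:.10g} {z:.10g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


# ---------------------------------------------------------------------------
# cloud utilities


def merge_clouds(clouds, frame_id: str = "world") -> PointCloud:
    """Concatenate clouds (they must already share a coordinate frame).

    Labels are kept only if every input carries them.
    """
    clouds = list(clouds)
    if not clouds:
        return PointCloud(np.empty((0, 3)), frame_id=frame_id)
    pts = np.vstack([c.points for c in clouds])
    labels = None
    if all(c.labels is not None for c in clouds):
        labels = np.concatenate([c.labels for c in clouds])
    return PointCloud(pts, labels, frame_id)


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Fuse a multi-station cloud by averaging points within cubic voxels.

    Points from different stations that sample the same patch of surface are
    collapsed into their centroid, which both removes the density imbalance
    between overlap regions and averages out range noise across stations.
    When labels are present, voxels are split per label so leaves touching
    each other are never fused together.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if len(cloud) == 0:
        return cloud
    ijk = np.floor(cloud.points / voxel_size).astype(np.int64)
    if cloud.labels is not None:
        keys = np.column_stack([cloud.labels, ijk])
    else:
        keys = ijk
    _uniq, inv, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inv, cloud.points)
    pts = sums / counts[:, None]
    labels = None
    if cloud.labels is not None:
        labels = np.zeros(len(counts), dtype=np.int64)
        labels[inv] = cloud.labels
    # keep deterministic order: sort by first occurrence in the input
    first = np.full(len(counts), len(cloud), dtype=np.int64)
    np.minimum.at(first, inv, np.arange(len(cloud)))
    order = np.argsort(first, kind="stable")
    return PointCloud(
        pts[order],
        None if labels is None else labels[order],
        cloud.frame_id,
    )
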