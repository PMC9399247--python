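"""Triangle-mesh data model, STL I/O and elementary geometric maps.

All coordinates are Cartesian millimetres with arbitrary origin.  Meshes use
counter-clockwise winding for outward normals; operations that invert
orientation (reflections) repair the winding so signed volume keeps its sign.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "RigidTransform",
    "ReflectionPlane",
    "LongAxis",
    "read_stl",
    "write_stl",
    "apply_rigid",
    "reflect",
    "long_axis_line",
    "decimate_grid",
]

_WELD_DECIMALS = 6  # vertex welding tolerance of 1e-6 mm on STL read


@dataclasses.dataclass
class TriangleMesh:
    """Indexed triangle surface: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")

    # -- derived quantities -------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward CCW winding."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def edges_unique(self) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclasses.dataclass
class RigidTransform:
    """Proper rigid map x -> R x + t (rotation ``R`` orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 (reflections excluded)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(
        cls, point: np.ndarray, direction: np.ndarray, angle: float
    ) -> "RigidTransform":
        """Rotation by ``angle`` (rad) about the line through ``point`` along ``direction``."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclasses.dataclass
class ReflectionPlane:
    """Mirror plane given by a point on the plane and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("zero-length plane normal")
        self.normal = n / norm


@dataclasses.dataclass
class LongAxis:
    """Tooth long axis: the line through the root apex and the crown midpoint."""

    apical_point: np.ndarray
    coronal_point: np.ndarray

    def __post_init__(self) -> None:
        self.apical_point = np.asarray(self.apical_point, dtype=float).reshape(3)
        self.coronal_point = np.asarray(self.coronal_point, dtype=float).reshape(3)
        if np.linalg.norm(self.coronal_point - self.apical_point) < 1e-12:
            raise ValueError("long-axis points coincide")

    @property
    def direction(self) -> np.ndarray:
        d = self.coronal_point - self.apical_point
        return d / np.linalg.norm(d)


def long_axis_line(axis: LongAxis) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction (apical -> coronal) and anchor point (the apex)."""
    return axis.direction, axis.apical_point.copy()


# ---------------------------------------------------------------------------
# STL I/O


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than the welding tolerance; drop degenerate faces."""
    key = np.round(vertices, _WELD_DECIMALS)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = vertices[first]
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces]


def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file (dialect auto-detected).

    Duplicate facet corners are welded at 1e-6 mm so the result is an indexed
    mesh rather than a triangle soup.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a mix of types on corrupt input
        raise ValueError(f"corrupt STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"empty mesh in {path}")
    verts, faces = _weld(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))
    if len(faces) == 0:
        raise ValueError(f"empty mesh in {path}")
    return TriangleMesh(verts, faces)


def write_stl(mesh: TriangleMesh, path: str | Path, format: str = "binary") -> Path:
    """Write ``mesh`` as STL. ``format`` is ``"binary"`` or ``"ascii"``."""
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write empty mesh")
    if format not in ("binary", "ascii"):
        raise ValueError(f"unknown STL format {format!r}")
    path = Path(path)
    tm = mesh.to_trimesh()
    file_type = "stl" if format == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# Transforms


def apply_rigid(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Apply a proper rigid transform to every vertex; faces unchanged."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy())


def reflect_points(points: np.ndarray, plane: ReflectionPlane) -> np.ndarray:
    p, n = plane.point, plane.normal
    d = (np.asarray(points, dtype=float) - p) @ n
    return points - 2.0 * d[:, None] * n


def reflect(mesh: TriangleMesh, plane: ReflectionPlane) -> TriangleMesh:
    """Mirror the mesh across ``plane``.

    Vertex map: v -> v - 2((v - p)·n) n.  Face winding is reversed afterwards
    so the mirrored surface keeps outward-facing normals.
    """
    verts = reflect_points(mesh.vertices, plane)
    return TriangleMesh(verts, mesh.faces[:, ::-1].copy())


# ---------------------------------------------------------------------------
# Decimation


def decimate_grid(mesh: TriangleMesh, cell: float) -> TriangleMesh:
    """Vertex-clustering decimation on a cubic grid of edge ``cell`` mm.

    All vertices falling in one grid cell collapse to their centroid;
    faces that become degenerate are removed.  Never increases vertex count,
    and displaces no vertex by more than ``cell * sqrt(3)``.
    """
    if cell <= 0:
        raise ValueError("grid cell size must be positive")
    keys = np.floor(mesh.vertices / cell).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_inverse=True, return_index=True)
    n_cells = first.size
    sums = np.zeros((n_cells, 3))
    np.add.at(sums, inverse, mesh.vertices)
    counts = np.bincount(inverse, minlength=n_cells).astype(float)
    centroids = sums / counts[:, None]
    faces = inverse[mesh.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    used = np.unique(faces) if len(faces) else np.arange(n_cells)
    remap = np.full(n_cells, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(centroids[used], remap[faces] if len(faces) else faces)
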