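"""Landmark superimposition, long-axis mirroring and constrained point-to-plane ICP.

Registration proceeds in two stages, as in the pair-matching workflow:

1. A closed-form least-squares rigid superimposition on three reference
   points (root apex and the two prominent incisal-edge points).
2. A *constrained* iterative closest point refinement.  The point-to-plane
   ICP is restricted to the residual freedom a mirrored contralateral pair
   actually has once long axes coincide: a rotation angle about the tooth's
   long axis and a translation in the plane perpendicular to it.  Each
   iteration solves the 3-parameter linearized point-to-plane problem; the
   accumulated transform satisfies the constraints exactly by construction.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .mesh import LongAxis, ReflectionPlane, RigidTransform, TriangleMesh, reflect
from .proximity import SurfaceLocator
from .similarity import sample_mesh_points

__all__ = [
    "LandmarkTriplet",
    "IcpConfig",
    "IcpResult",
    "IcpTarget",
    "landmark_align",
    "mirror_along_long_axis",
    "default_mirror_normal",
    "perpendicular_basis",
    "constrained_icp",
]


@dataclasses.dataclass
class LandmarkTriplet:
    """Reference points: root apex + the two prominent incisal-edge points."""

    apical: np.ndarray
    incisal_left: np.ndarray
    incisal_right: np.ndarray

    def __post_init__(self) -> None:
        self.apical = np.asarray(self.apical, dtype=float).reshape(3)
        self.incisal_left = np.asarray(self.incisal_left, dtype=float).reshape(3)
        self.incisal_right = np.asarray(self.incisal_right, dtype=float).reshape(3)
        a = np.linalg.norm(
            np.cross(
                self.incisal_left - self.apical, self.incisal_right - self.apical
            )
        ) / 2.0
        if a <= 1e-6:
            raise ValueError("landmark triplet is collinear")

    def as_array(self) -> np.ndarray:
        return np.vstack([self.apical, self.incisal_left, self.incisal_right])

    def transformed(self, transform: RigidTransform) -> "LandmarkTriplet":
        p = transform.apply(self.as_array())
        return LandmarkTriplet(p[0], p[1], p[2])


@dataclasses.dataclass
class IcpConfig:
    """Free parameters of the constrained ICP."""

    max_iterations: int = 100
    convergence_tol: float = 1e-6  # mm change in point-to-plane RMS
    correspondence_cap: float = 2.0  # mm; reject farther pairs
    sample_count: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if (
            self.max_iterations <= 0
            or self.convergence_tol <= 0
            or self.correspondence_cap <= 0
            or self.sample_count <= 0
        ):
            raise ValueError("all ICP parameters must be positive")


def landmark_align(source: LandmarkTriplet, target: LandmarkTriplet) -> RigidTransform:
    """Closed-form least-squares rigid superimposition of two landmark triplets.

    Kabsch solution via SVD of the cross-covariance; reflections are excluded
    by the determinant correction, so the result is always a proper rotation.
    """
    s = source.as_array()
    t = target.as_array()
    cs, ct = s.mean(axis=0), t.mean(axis=0)
    H = (s - cs).T @ (t - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def perpendicular_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal basis (e1, e2) of the plane perpendicular to ``direction``."""
    a = np.asarray(direction, dtype=float)
    a = a / np.linalg.norm(a)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(a @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ a) * a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def default_mirror_normal(axis: LongAxis, reference=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Mesiodistal mirror normal: ``reference`` orthogonalized against the axis."""
    a = axis.direction
    r = np.asarray(reference, dtype=float)
    n = r - (r @ a) * a
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("reference direction is parallel to the long axis")
    return n / norm


def mirror_along_long_axis(
    mesh: TriangleMesh, axis: LongAxis, mirror_normal: np.ndarray | None = None
) -> TriangleMesh:
    """Mirror a tooth across the plane containing its long axis.

    The plane passes through the axis with normal ``mirror_normal``
    (default: the mesiodistal x direction orthogonalized against the axis),
    so every point of the long axis is fixed.
    """
    if mirror_normal is None:
        n = default_mirror_normal(axis)
    else:
        n = np.asarray(mirror_normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        if abs(n @ axis.direction) > 1e-6:
            raise ValueError("mirror normal must be perpendicular to the long axis")
    return reflect(mesh, ReflectionPlane(axis.apical_point, n))


# ---------------------------------------------------------------------------
# Constrained ICP


class IcpTarget:
    """Correspondence provider for the ICP target surface.

    mode="points": nearest target sample point with its (vertex or face)
    normal — fast, used for population-scale runs.
    mode="mesh": exact closest point on the target triangles with the face
    normal — used where sub-1e-3 recovery matters.
    """

    def __init__(self, mesh: TriangleMesh, mode: str = "points", extra_samples: int = 0, seed: int = 0):
        self.mesh = mesh
        self.mode = mode
        if mode == "points":
            tm = mesh.to_trimesh()
            pts = [np.asarray(mesh.vertices)]
            normals = [np.asarray(tm.vertex_normals, dtype=float)]
            if extra_samples > 0:
                area = mesh.area()
                density = extra_samples / max(area, 1e-12)
                extra = sample_mesh_points(mesh, density, seed)[len(mesh.vertices):]
                if len(extra):
                    loc = SurfaceLocator(mesh)
                    _, _, fi = loc.query(extra)
                    pts.append(extra)
                    normals.append(loc.face_normal(fi))
            self.points = np.vstack(pts)
            self.normals = np.vstack(normals)
            self._tree = cKDTree(self.points)
        elif mode == "mesh":
            self._locator = SurfaceLocator(mesh)
        else:
            raise ValueError(f"unknown IcpTarget mode {mode!r}")

    def correspond(self, points: np.ndarray):
        """Return (closest point, normal, distance) per query point."""
        if self.mode == "points":
            d, idx = self._tree.query(points, k=1)
            return self.points[idx], self.normals[idx], d
        close, d, fi = self._locator.query(points)
        return close, self._locator.face_normal(fi), d


@dataclasses.dataclass
class IcpResult:
    transform: RigidTransform
    rms: float
    theta: float  # rotation angle about the long axis (rad)
    in_plane: np.ndarray  # accumulated translation in the perpendicular plane (mm)
    iterations: int
    rms_history: list
    inner_decrease: list  # per-iteration linearized objective decrease flags


def _constraint_transform(
    theta: float, t_vec: np.ndarray, anchor: np.ndarray, direction: np.ndarray
) -> RigidTransform:
    rot = RigidTransform.about_axis(anchor, direction, theta)
    return RigidTransform(rot.rotation, rot.translation + t_vec)


def constrained_icp(
    source: TriangleMesh,
    target: TriangleMesh | IcpTarget,
    axis: LongAxis,
    config: IcpConfig | None = None,
    source_points: np.ndarray | None = None,
) -> IcpResult:
    """Constrained point-to-plane ICP restricted to the long-axis motion group.

    Solves, per iteration, the linearized point-to-plane least squares over
    (theta, u, v): rotation ``theta`` about the long axis and translation
    ``(u, v)`` in the plane perpendicular to it.  The accumulated transform
    is composed exactly within the constraint group, so the returned map has
    no rotation component off the axis and no translation along it.
    """
    config = config or IcpConfig()
    tgt = target if isinstance(target, IcpTarget) else IcpTarget(target)
    a = axis.direction
    p = axis.apical_point
    e1, e2 = perpendicular_basis(a)

    if source_points is None:
        if config.sample_count >= len(source.vertices):
            base = np.asarray(source.vertices)
        else:
            rng = np.random.default_rng(config.seed)
            idx = rng.choice(len(source.vertices), config.sample_count, replace=False)
            base = np.asarray(source.vertices)[idx]
    else:
        base = np.asarray(source_points, dtype=float).reshape(-1, 3)

    theta = 0.0
    t_vec = np.zeros(3)
    prev_rms = None
    rms = np.inf
    history: list[float] = []
    inner: list[bool] = []
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        current = _constraint_transform(theta, t_vec, p, a).apply(base)
        q, n, d = tgt.correspond(current)
        mask = d <= config.correspondence_cap
        if not mask.any():
            raise ValueError("no ICP correspondences survive the distance cap")
        cp, cq, cn = current[mask], q[mask], n[mask]
        r = np.einsum("ij,ij->i", cn, cp - cq)
        rms = float(np.sqrt(np.mean(r**2)))
        history.append(rms)
        J = np.column_stack(
            [
                np.einsum("ij,ij->i", cn, np.cross(a, cp - p)),
                cn @ e1,
                cn @ e2,
            ]
        )
        JtJ = J.T @ J
        Jtr = J.T @ r
        try:
            x = np.linalg.solve(JtJ, -Jtr)
        except np.linalg.LinAlgError:
            x, *_ = np.linalg.lstsq(J, -r, rcond=None)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite ICP solve")
        inner.append(float(np.mean((r + J @ x) ** 2)) <= float(np.mean(r**2)) + 1e-15)
        d_theta = float(x[0])
        d_t = x[1] * e1 + x[2] * e2
        rot = RigidTransform.about_axis(np.zeros(3), a, d_theta)
        theta += d_theta
        t_vec = rot.rotation @ t_vec + d_t
        if prev_rms is not None and abs(prev_rms - rms) < config.convergence_tol:
            break
        prev_rms = rms

    transform = _constraint_transform(theta, t_vec, p, a)
    final = transform.apply(base)
    q, n, d = tgt.correspond(final)
    mask = d <= config.correspondence_cap
    r = np.einsum("ij,ij->i", n[mask], final[mask] - q[mask])
    rms = float(np.sqrt(np.mean(r**2)))
    return IcpResult(transform, rms, theta, t_vec, iterations, history, inner)
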