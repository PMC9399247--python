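"""Hausdorff-distance shape similarity between sampled element surfaces.

The similarity score used throughout is the symmetric Hausdorff distance
between two point sets: the larger of the two directed distances
``max_a min_b |a - b|``.  Point sets are an element's mesh vertices plus an
optional area-weighted uniform sample of its faces.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SampledSurface",
    "sample_surface",
    "sample_mesh_points",
    "directed_hausdorff",
    "symmetric_hausdorff",
]


@dataclasses.dataclass
class SampledSurface:
    """Point sample of one tooth-element surface (mm)."""

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("empty point sample")


def sample_mesh_points(
    mesh, density: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Mesh vertices plus ``ceil(density * area)`` uniform random face points.

    Face points are area-weighted with the square-root barycentric trick so
    the sample is uniform over the surface; fully reproducible from ``seed``.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if len(mesh.faces) == 0:
        raise ValueError("cannot sample an empty element")
    pts = [mesh.vertices]
    n_extra = math.ceil(density * mesh.area())
    if n_extra > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        areas = mesh.face_areas()
        probs = areas / areas.sum()
        fi = rng.choice(len(probs), size=n_extra, p=probs)
        r1 = np.sqrt(rng.random(n_extra))
        r2 = rng.random(n_extra)
        t = mesh.triangles[fi]
        extra = (
            (1 - r1)[:, None] * t[:, 0]
            + (r1 * (1 - r2))[:, None] * t[:, 1]
            + (r1 * r2)[:, None] * t[:, 2]
        )
        pts.append(extra)
    return np.vstack(pts)


def sample_surface(element, density: float = 10.0, seed: int = 0) -> SampledSurface:
    """Sample a :class:`~toothpair.annotation.ToothElement` surface.

    ``density`` is in points per mm^2; ``density=0`` returns exactly the
    vertex set.
    """
    mesh = getattr(element, "mesh", element)
    source = getattr(element, "element_kind", "")
    tooth = getattr(element, "tooth_id", "")
    return SampledSurface(
        sample_mesh_points(mesh, density, seed), source_id=f"{tooth}:{source}"
    )


def _points(surface) -> np.ndarray:
    if isinstance(surface, SampledSurface):
        return surface.points
    pts = np.asarray(surface, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    return pts


def directed_hausdorff(A, B) -> float:
    """max over a in A of the distance from a to its nearest point of B (mm)."""
    a, b = _points(A), _points(B)
    d, _ = cKDTree(b).query(a, k=1)
    return float(d.max())


def symmetric_hausdorff(A, B) -> float:
    """Symmetric Hausdorff distance: max of the two directed distances (mm)."""
    return max(directed_hausdorff(A, B), directed_hausdorff(B, A))
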