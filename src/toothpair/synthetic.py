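"""Seeded generator of bilateral anterior-tooth populations.

Stands in for a patient cohort: each synthetic individual has six maxillary
anterior teeth (central incisor, lateral incisor, canine; right and left).
A tooth is a watertight surface of revolution-like solid in a local frame
(+z = long axis with the root apex at the origin, x = mesiodistal,
y = faciolingual): a tapered root blending into a bulged superellipse-section
crown, with a scalloped gingival margin at the cervix.

Shape variation is a smooth low-order radial deformation field (angular x
axial harmonics), not vertex noise: per-individual coefficients are drawn
with SD ``sigma_pop`` and the left side is the exact mirror image of the
right plus an extra draw with SD ``sigma_asym``.  Inter-individual variation
therefore dominates within-individual (left/right) asymmetry whenever
``sigma_asym < sigma_pop``, which is the regime the pair-matching study
operates in.  Everything is deterministic given the seeds.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .annotation import SurfaceCurve
from .mesh import LongAxis, ReflectionPlane, TriangleMesh, read_stl, reflect, write_stl
from .model import SIDES, TOOTH_TYPES, ToothModel
from .proximity import SurfaceLocator
from .registration import LandmarkTriplet

__all__ = [
    "ToothShapeParams",
    "PopulationConfig",
    "Population",
    "default_params",
    "generate_tooth",
    "generate_individual",
    "generate_population",
    "load_population",
    "N_DEFORM_COEFFS",
]

# deformation basis: cos(m*theta)*cos(l*pi*u) for m,l in 0..2 plus the
# sin(m*theta) partners for m in 1..2  ->  15 coefficients
_ANGULAR = [(m, kind) for m in range(3) for kind in (("cos",) if m == 0 else ("cos", "sin"))]
_AXIAL = 3
N_DEFORM_COEFFS = len(_ANGULAR) * _AXIAL


@dataclasses.dataclass
class ToothShapeParams:
    """Anatomy of one tooth type (all lengths mm)."""

    tooth_type: str
    crown_height: float
    root_height: float
    mesiodistal_radius: float
    faciolingual_radius: float
    crown_bulge: float = 0.12
    superellipse_exponent: float = 3.0
    scallop_amplitude: float = 1.5
    cusp_height: float = 0.0
    incisal_taper: float = 0.25

    def __post_init__(self) -> None:
        if min(
            self.crown_height,
            self.root_height,
            self.mesiodistal_radius,
            self.faciolingual_radius,
        ) <= 0:
            raise ValueError("heights and radii must be positive")

    @property
    def total_height(self) -> float:
        return self.crown_height + self.root_height


def default_params(tooth_type: str) -> ToothShapeParams:
    """Typical maxillary anterior crown/root dimensions per tooth type."""
    if tooth_type == "central":
        return ToothShapeParams("central", 10.5, 13.0, 4.2, 3.5, 0.12, 3.0, 1.5, 0.0, 0.25)
    if tooth_type == "lateral":
        return ToothShapeParams("lateral", 9.0, 13.0, 3.3, 3.0, 0.12, 3.0, 1.3, 0.0, 0.30)
    if tooth_type == "canine":
        return ToothShapeParams("canine", 10.0, 16.0, 3.8, 4.0, 0.15, 2.5, 1.5, 1.5, 0.55)
    raise ValueError(f"unknown tooth type {tooth_type!r}")


@dataclasses.dataclass
class PopulationConfig:
    """Study-population settings for the synthetic cohort."""

    n_individuals: int = 100
    sigma_pop: float = 0.5  # mm SD of inter-individual deformation coefficients
    sigma_asym: float = 0.05  # mm SD of the extra left-side (asymmetry) draw
    resolution: tuple[int, int] = (64, 64)  # angular x axial samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.sigma_pop < 0 or self.sigma_asym < 0:
            raise ValueError("sigmas must be non-negative")
        if min(self.resolution) < 8:
            raise ValueError("resolution must be at least 8x8")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution"] = list(self.resolution)
        return d


@dataclasses.dataclass
class Population:
    """In-memory synthetic cohort: per individual a (tooth_type, side) -> ToothModel map."""

    individuals: list
    config: PopulationConfig

    @property
    def ids(self) -> list:
        return [ind["id"] for ind in self.individuals]

    def teeth(self, tooth_type: str, side: str) -> dict:
        return {
            ind["id"]: ind["teeth"][(tooth_type, side)] for ind in self.individuals
        }


# ---------------------------------------------------------------------------
# Parametric geometry


def _superellipse_radius(theta, a, b, n):
    return (np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n) ** (
        -1.0 / n
    )


def _axial_profile(z, params: ToothShapeParams):
    z = np.asarray(z, dtype=float)
    zr, hc = params.root_height, params.crown_height
    s = np.empty_like(z)
    root = z <= zr
    s[root] = (np.clip(z[root] / zr, 0, 1)) ** 0.7
    w = np.clip((z[~root] - zr) / hc, 0, 1)
    s[~root] = (1 + params.crown_bulge * np.sin(np.pi * w)) * (
        1 - params.incisal_taper * w**2
    )
    return s


def _deformation(theta, u, coefficients):
    """Radial displacement field (mm) from the low-order harmonic coefficients."""
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if c.size != N_DEFORM_COEFFS:
        raise ValueError(f"expected {N_DEFORM_COEFFS} deformation coefficients")
    delta = np.zeros_like(theta)
    i = 0
    for m, kind in _ANGULAR:
        ang = np.cos(m * theta) if kind == "cos" else np.sin(m * theta)
        for l in range(_AXIAL):
            delta = delta + c[i] * ang * np.cos(l * np.pi * u)
            i += 1
    return delta * np.sqrt(np.clip(u, 0, 1))  # window: zero at the apex


def _radius(theta, z, params: ToothShapeParams, coefficients):
    base = _superellipse_radius(
        theta, params.mesiodistal_radius, params.faciolingual_radius,
        params.superellipse_exponent,
    ) * _axial_profile(z, params)
    u = np.asarray(z, dtype=float) / params.total_height
    return np.maximum(base + _deformation(theta, u, coefficients), 0.3)


def _build_mesh(params: ToothShapeParams, resolution, coefficients) -> TriangleMesh:
    n_theta, n_z = resolution
    H = params.total_height
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = H * np.arange(1, n_z + 1) / n_z
    tt, zz = np.meshgrid(thetas, zs)
    rr = _radius(tt, zz, params, coefficients)
    ring_verts = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(), zz.ravel()]
    )
    apex = np.zeros((1, 3))
    top = np.array([[0.0, 0.0, H + params.cusp_height]])
    vertices = np.vstack([apex, ring_verts, top])
    top_idx = len(vertices) - 1

    def ring(j, i):
        return 1 + j * n_theta + (i % n_theta)

    faces = []
    for i in range(n_theta):
        faces.append([0, ring(0, i + 1), ring(0, i)])
    for j in range(n_z - 1):
        for i in range(n_theta):
            a, b = ring(j, i), ring(j, i + 1)
            c, d = ring(j + 1, i + 1), ring(j + 1, i)
            faces.append([a, b, c])
            faces.append([a, c, d])
    for i in range(n_theta):
        faces.append([top_idx, ring(n_z - 1, i), ring(n_z - 1, i + 1)])
    mesh = TriangleMesh(vertices, np.asarray(faces))
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _landmarks(
    mesh: TriangleMesh, params: ToothShapeParams, resolution
) -> tuple[LandmarkTriplet, LongAxis]:
    """Annotate the apex and the two mesiodistal incisal-edge points.

    The incisal points are the top-ring vertices at the mesial and distal
    parametric extremes (theta = 0 and pi): anatomically corresponding
    material points that stay matched across deformation and mirroring, as a
    manual annotator marking the same anatomy on both sides would produce.
    """
    n_theta, n_z = resolution
    verts = mesh.vertices
    apex = verts[np.argmin(verts[:, 2])]
    i0 = 1 + (n_z - 1) * n_theta  # top ring, theta = 0
    i_half = i0 + n_theta // 2  # top ring, theta = pi
    a, b = verts[i0], verts[i_half]
    incisal_right, incisal_left = (a, b) if a[0] >= b[0] else (b, a)
    crown_verts = verts[verts[:, 2] > params.root_height]
    coronal = crown_verts.mean(axis=0)
    triplet = LandmarkTriplet(apex, incisal_left, incisal_right)
    return triplet, LongAxis(apex, coronal)


def _gingival_curve(
    mesh: TriangleMesh,
    params: ToothShapeParams,
    coefficients,
    n_samples: int,
    mirror_x: bool = False,
    asym_coefficients=None,
) -> SurfaceCurve:
    thetas = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    zg = params.root_height + params.scallop_amplitude * np.cos(2 * thetas)
    r = _radius(thetas, zg, params, coefficients)
    pts = np.column_stack([r * np.cos(thetas), r * np.sin(thetas), zg])
    if mirror_x:
        pts[:, 0] = -pts[:, 0]
        pts = pts[::-1].copy()  # keep a consistent orientation after mirroring
    if asym_coefficients is not None:
        pts = _apply_radial_deformation(pts, params, asym_coefficients)
    pts = np.vstack([pts, pts[:1]])
    locator = SurfaceLocator(mesh)
    proj, _, faces = locator.query(pts)
    proj[-1] = proj[0]
    faces[-1] = faces[0]
    bary = locator.barycentric(proj, faces)
    return SurfaceCurve(proj, faces, bary, closed=True)


def _apply_radial_deformation(points: np.ndarray, params: ToothShapeParams, coefficients):
    """Displace points radially by the harmonic field (axis points are fixed)."""
    pts = np.array(points, dtype=float)
    radial = np.hypot(pts[:, 0], pts[:, 1])
    ok = radial > 1e-9
    theta = np.arctan2(pts[ok, 1], pts[ok, 0])
    u = pts[ok, 2] / params.total_height
    delta = _deformation(theta, u, coefficients)
    scale = np.maximum(radial[ok] + delta, 0.3) / radial[ok]
    pts[ok, 0] *= scale
    pts[ok, 1] *= scale
    return pts


def generate_tooth(
    params: ToothShapeParams,
    resolution=(64, 64),
    coefficients=None,
    individual_id: str = "tooth0",
    side: str = "right",
) -> ToothModel:
    """Build one right-side tooth in its local frame.

    ``coefficients`` (length 15, mm) drive the radial deformation field;
    ``None`` gives the undeformed base anatomy.
    """
    if coefficients is None:
        coefficients = np.zeros(N_DEFORM_COEFFS)
    mesh = _build_mesh(params, resolution, coefficients)
    landmarks, axis = _landmarks(mesh, params, resolution)
    curve = _gingival_curve(mesh, params, coefficients, 2 * resolution[0])
    return ToothModel(individual_id, params.tooth_type, side, mesh, landmarks, curve, axis)


def _mirror_tooth(
    right: ToothModel,
    params: ToothShapeParams,
    right_coeffs,
    asym_coeffs,
    resolution,
) -> ToothModel:
    """Left tooth: exact mirror (x -> -x) of the right geometry plus asymmetry noise."""
    plane = ReflectionPlane(np.zeros(3), np.array([1.0, 0.0, 0.0]))
    mesh = reflect(right.mesh, plane)
    mesh = TriangleMesh(
        _apply_radial_deformation(mesh.vertices, params, asym_coeffs), mesh.faces
    )
    landmarks, axis = _landmarks(mesh, params, resolution)
    curve = _gingival_curve(
        mesh, params, right_coeffs, 2 * resolution[0],
        mirror_x=True, asym_coefficients=asym_coeffs,
    )
    return ToothModel(
        right.individual_id, right.tooth_type, "left", mesh, landmarks, curve, axis
    )


def generate_individual(
    cfg: PopulationConfig,
    individual_seed: np.random.SeedSequence | int,
    individual_id: str,
    base_params: dict | None = None,
) -> dict:
    """Six teeth (3 types x 2 sides) for one individual; deterministic given seeds."""
    base_params = base_params or {t: default_params(t) for t in TOOTH_TYPES}
    ss = (
        individual_seed
        if isinstance(individual_seed, np.random.SeedSequence)
        else np.random.SeedSequence(individual_seed)
    )
    rng = np.random.default_rng(ss)
    teeth = {}
    for tooth_type in TOOTH_TYPES:
        params = base_params[tooth_type]
        c_right = rng.normal(0.0, cfg.sigma_pop, N_DEFORM_COEFFS)
        c_asym = rng.normal(0.0, cfg.sigma_asym, N_DEFORM_COEFFS)
        right = generate_tooth(
            params, cfg.resolution, c_right, individual_id, "right"
        )
        left = _mirror_tooth(right, params, c_right, c_asym, cfg.resolution)
        teeth[(tooth_type, "right")] = right
        teeth[(tooth_type, "left")] = left
    return {"id": individual_id, "teeth": teeth}


def generate_population(
    cfg: PopulationConfig,
    base_params: dict | None = None,
    out_dir: str | Path | None = None,
) -> Population:
    """Generate the full cohort; optionally write STL files + JSON manifest."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_individuals)
    individuals = [
        generate_individual(cfg, child, f"ind{i:03d}", base_params)
        for i, child in enumerate(children)
    ]
    pop = Population(individuals, cfg)
    if out_dir is not None:
        write_population(pop, out_dir)
    return pop


def write_population(pop: Population, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": pop.config.to_dict(), "individuals": []}
    for ind in pop.individuals:
        rec = {"id": ind["id"], "teeth": []}
        for (tooth_type, side), tooth in sorted(ind["teeth"].items()):
            name = f"{ind['id']}_{tooth_type}_{side}.stl"
            write_stl(tooth.mesh, out_dir / name, format="binary")
            rec["teeth"].append(
                {
                    "tooth_type": tooth_type,
                    "side": side,
                    "path": name,
                    "landmarks": {
                        "apical": tooth.landmarks.apical.tolist(),
                        "incisal_left": tooth.landmarks.incisal_left.tolist(),
                        "incisal_right": tooth.landmarks.incisal_right.tolist(),
                    },
                    "long_axis": {
                        "apical": tooth.long_axis.apical_point.tolist(),
                        "coronal": tooth.long_axis.coronal_point.tolist(),
                    },
                    "gingival_margin": tooth.gingival_margin.to_dict(),
                }
            )
        manifest["individuals"].append(rec)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh)
    return out_dir / "manifest.json"


def load_population(manifest_path: str | Path) -> Population:
    """Round-trip a written population from its manifest and STL files."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    cfgd = dict(manifest["config"])
    cfgd["resolution"] = tuple(cfgd["resolution"])
    cfg = PopulationConfig(**cfgd)
    individuals = []
    for rec in manifest["individuals"]:
        teeth = {}
        for t in rec["teeth"]:
            mesh = read_stl(base / t["path"])
            lm = t["landmarks"]
            ax = t["long_axis"]
            teeth[(t["tooth_type"], t["side"])] = ToothModel(
                rec["id"],
                t["tooth_type"],
                t["side"],
                mesh,
                LandmarkTriplet(lm["apical"], lm["incisal_left"], lm["incisal_right"]),
                SurfaceCurve.from_dict(t["gingival_margin"]),
                LongAxis(ax["apical"], ax["coronal"]),
            )
        individuals.append({"id": rec["id"], "teeth": teeth})
    return Population(individuals, cfg)
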