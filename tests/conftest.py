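import numpy as np
import pytest
import trimesh

from toothpair.mesh import TriangleMesh
from toothpair.synthetic import default_params, generate_tooth


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture
def unit_cube() -> TriangleMesh:
    box = trimesh.creation.box(extents=(1, 1, 1))
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture
def sphere() -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def clean_central_tooth():
    """Undeformed central incisor at moderate resolution (zero asymmetry)."""
    return generate_tooth(default_params("central"), resolution=(32, 32))


@pytest.fixture
def flat_grid() -> TriangleMesh:
    """Fine planar mesh covering [-15, 15]^2 at z = 0."""
    n = 61
    xs = np.linspace(-15, 15, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces.append([a, a + 1, a + n + 1])
            faces.append([a, a + n + 1, a + n])
    return TriangleMesh(verts, np.asarray(faces))


@pytest.fixture
def cylinder_grid() -> TriangleMesh:
    """Open cylinder of radius 4, z in [-6, 2], structured grid."""
    n_theta, n_z = 48, 33
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(-6, 2, n_z)
    tt, zz = np.meshgrid(thetas, zs)
    verts = np.column_stack(
        [4 * np.cos(tt).ravel(), 4 * np.sin(tt).ravel(), zz.ravel()]
    )
    faces = []
    for j in range(n_z - 1):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = (j + 1) * n_theta + (i + 1) % n_theta
            d = (j + 1) * n_theta + i
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangleMesh(verts, np.asarray(faces))
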