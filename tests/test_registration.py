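import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from toothpair.mesh import RigidTransform, apply_rigid
from toothpair.registration import (
    IcpConfig,
    IcpTarget,
    LandmarkTriplet,
    constrained_icp,
    landmark_align,
    mirror_along_long_axis,
    perpendicular_basis,
)
from toothpair.similarity import symmetric_hausdorff


def _random_triplet(rng):
    while True:
        p = rng.normal(0, 5, (3, 3))
        try:
            return LandmarkTriplet(*p)
        except ValueError:
            continue


class TestLandmarkAlign:
    def test_identity(self):
        t = LandmarkTriplet([0, 0, 0], [-3, 0, 20], [3, 0, 20])
        out = landmark_align(t, t)
        assert np.allclose(out.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(out.translation, 0, atol=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(7)
        src = _random_triplet(rng)
        truth = RigidTransform.about_axis([1, 2, 3], [0.3, -1, 0.5], 0.9)
        truth = RigidTransform(truth.rotation, truth.translation + [0.4, -2, 1])
        out = landmark_align(src, src.transformed(truth))
        assert np.allclose(out.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(out.translation, truth.translation, atol=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            LandmarkTriplet([0, 0, 0], [1, 1, 1], [2, 2, 2])

    def test_matches_numeric_minimization(self):
        """Closed form equals a rotation-vector parameterized numeric optimum."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            src, tgt = _random_triplet(rng), _random_triplet(rng)
            closed = landmark_align(src, tgt)

            def objective(x):
                R = Rotation.from_rotvec(x[:3]).as_matrix()
                res = src.as_array() @ R.T + x[3:] - tgt.as_array()
                return (res**2).sum()

            best = min(
                (
                    minimize(objective, x0, method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
                    for x0 in [np.zeros(6), rng.normal(0, 1, 6), rng.normal(0, 1, 6)]
                ),
                key=lambda r: r.fun,
            )
            closed_obj = (
                (src.as_array() @ closed.rotation.T + closed.translation - tgt.as_array())
                ** 2
            ).sum()
            assert closed_obj <= best.fun + 1e-6


class TestMirrorAlongLongAxis:
    def test_axis_fixed_and_involution(self, clean_central_tooth):
        tooth = clean_central_tooth
        mirrored = mirror_along_long_axis(tooth.mesh, tooth.long_axis)
        twice = mirror_along_long_axis(mirrored, tooth.long_axis)
        assert np.allclose(twice.vertices, tooth.mesh.vertices, atol=1e-12)

    def test_symmetric_tooth_maps_to_itself(self, clean_central_tooth):
        """Zero deformation builds a mesh symmetric about the mirror plane."""
        tooth = clean_central_tooth
        mirrored = mirror_along_long_axis(tooth.mesh, tooth.long_axis, [1, 0, 0])
        assert symmetric_hausdorff(tooth.mesh.vertices, mirrored.vertices) < 1e-9

    def test_non_perpendicular_normal_rejected(self, clean_central_tooth):
        tooth = clean_central_tooth
        with pytest.raises(ValueError):
            mirror_along_long_axis(tooth.mesh, tooth.long_axis, [0.2, 0, 1.0])


def grid_search_objective(points, target: IcpTarget, axis, cap):
    """Independent brute-force constrained point-to-plane objective."""
    a = axis.direction
    p = axis.apical_point
    e1, e2 = perpendicular_basis(a)

    def rms(theta, u, v):
        R = Rotation.from_rotvec(theta * a).as_matrix()
        moved = (points - p) @ R.T + p + u * e1 + v * e2
        q, n, d = target.correspond(moved)
        m = d <= cap
        r = np.einsum("ij,ij->i", n[m], moved[m] - q[m])
        return float(np.sqrt(np.mean(r**2)))

    return rms


def refine_grid_minimum(rms, center=(0.0, 0.0, 0.0), spans=(0.3, 2.0, 2.0)):
    """Coarse-to-fine (theta, u, v) grid search ending at 0.01 resolution."""
    c = np.asarray(center, dtype=float)
    spans = np.asarray(spans, dtype=float)
    best = None
    for level in range(3):
        axes = [np.linspace(ci - s, ci + s, 9) for ci, s in zip(c, spans)]
        vals = {}
        for th in axes[0]:
            for u in axes[1]:
                for v in axes[2]:
                    vals[(th, u, v)] = rms(th, u, v)
        key = min(vals, key=vals.get)
        best = vals[key]
        c = np.asarray(key)
        spans = np.maximum(spans / 4, 0.01 * 4)
    # final pass at exactly 0.01 step
    axes = [np.arange(ci - 0.04, ci + 0.045, 0.01) for ci in c]
    for th in axes[0]:
        for u in axes[1]:
            for v in axes[2]:
                best = min(best, rms(th, u, v))
    return best


class TestConstrainedIcp:
    def test_fixed_point(self, clean_central_tooth):
        mesh = clean_central_tooth.mesh
        res = constrained_icp(
            mesh, mesh, clean_central_tooth.long_axis,
            IcpConfig(sample_count=500, max_iterations=20),
        )
        assert res.rms < 1e-6
        assert abs(res.theta) < 1e-6
        assert np.linalg.norm(res.in_plane) < 1e-6

    def test_recovers_in_constraint_motion(self, clean_central_tooth):
        tooth = clean_central_tooth
        axis = tooth.long_axis
        a = axis.direction
        e1, e2 = perpendicular_basis(a)
        theta, u, v = np.deg2rad(5.0), 0.5, -0.3
        truth = RigidTransform.about_axis(axis.apical_point, a, theta)
        truth = RigidTransform(truth.rotation, truth.translation + u * e1 + v * e2)
        target = IcpTarget(apply_rigid(tooth.mesh, truth), mode="mesh")
        res = constrained_icp(
            tooth.mesh, target, axis,
            IcpConfig(sample_count=800, max_iterations=100, convergence_tol=1e-9),
        )
        assert abs(res.theta - theta) < 1e-3
        assert abs(res.in_plane @ e1 - u) < 1e-3
        assert abs(res.in_plane @ e2 - v) < 1e-3

    def test_constraints_hold_exactly(self, clean_central_tooth):
        tooth = clean_central_tooth
        axis = tooth.long_axis
        shifted = apply_rigid(
            tooth.mesh, RigidTransform(np.eye(3), 0.8 * axis.direction)
        )
        res = constrained_icp(tooth.mesh, shifted, axis, IcpConfig(sample_count=300))
        a = axis.direction
        # rotation leaves the axis direction invariant
        assert np.allclose(res.transform.rotation @ a, a, atol=1e-9)
        # no net translation along the axis
        p = axis.apical_point
        moved_anchor = res.transform.apply(p[None])[0]
        assert abs((moved_anchor - p) @ a) < 1e-9

    def test_inner_solve_decreases_objective(self, clean_central_tooth):
        tooth = clean_central_tooth
        axis = tooth.long_axis
        truth = RigidTransform.about_axis(axis.apical_point, axis.direction, 0.05)
        res = constrained_icp(
            tooth.mesh, apply_rigid(tooth.mesh, truth), axis,
            IcpConfig(sample_count=400),
        )
        assert all(res.inner_decrease)

    def test_out_of_constraint_motion_matches_grid_oracle(self, clean_central_tooth):
        """Translation along the axis cannot be compensated; the residual still
        matches the brute-force minimum of the constrained objective."""
        tooth = clean_central_tooth
        axis = tooth.long_axis
        shifted = apply_rigid(
            tooth.mesh, RigidTransform(np.eye(3), 1.0 * axis.direction)
        )
        target = IcpTarget(shifted, mode="mesh")
        cfg = IcpConfig(sample_count=200, max_iterations=60, convergence_tol=1e-8)
        rng = np.random.default_rng(3)
        idx = rng.choice(len(tooth.mesh.vertices), 200, replace=False)
        pts = np.asarray(tooth.mesh.vertices)[idx]
        res = constrained_icp(tooth.mesh, target, axis, cfg, source_points=pts)
        rms = grid_search_objective(pts, target, axis, cfg.correspondence_cap)
        oracle = refine_grid_minimum(rms)
        assert res.rms >= oracle * 0.95
        assert res.rms <= oracle * 1.05
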