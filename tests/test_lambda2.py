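import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import vortexflow as vf
from vortexflow.lambda2 import (
    _lambda2_from_jacobian,
    eigvalsh3,
    jacobian_lattice,
    lambda2_at,
    lambda2_at_points,
    velocity_jacobian,
)
from vortexflow.phantom import analytic_velocity, build_phantom_field, canonical_spec

from conftest import make_rigid_rotation, make_shear, make_uniform


class TestEigenSolver:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_lapack_on_random_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        M = A + A.T
        mine = eigvalsh3(M)
        ref = np.linalg.eigvalsh(M)
        scale = max(1.0, np.abs(ref).max())
        np.testing.assert_allclose(mine, ref, atol=1e-9 * scale)

    def test_sorted_ascending_batched(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(100, 3, 3))
        M = A + np.swapaxes(A, -1, -2)
        lam = eigvalsh3(M)
        assert (np.diff(lam, axis=-1) >= -1e-12).all()

    def test_degenerate_multiple(self):
        np.testing.assert_allclose(eigvalsh3(2.5 * np.eye(3)), [2.5, 2.5, 2.5])


class TestJacobian:
    def test_rigid_rotation_jacobian(self):
        field = make_rigid_rotation(omega=5.0)
        J = velocity_jacobian(field, 0, voxel=(4, 4, 4))
        np.testing.assert_allclose(J, [[0, -5, 0], [5, 0, 0], [0, 0, 0]], atol=1e-12)

    def test_uniform_flow_jacobian_zero(self):
        J = velocity_jacobian(make_uniform(), 0, voxel=(4, 4, 4))
        np.testing.assert_array_equal(J, np.zeros((3, 3)))

    def test_linear_stretch(self):
        xs = np.arange(9) - 4.0
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        field = vf.VelocityField4D((2 * X)[None], np.zeros_like(X)[None],
                                   np.zeros_like(X)[None], spacing=1.0, origin=(xs[0],) * 3)
        J = velocity_jacobian(field, 0, voxel=(4, 4, 4))
        expect = np.zeros((3, 3))
        expect[0, 0] = 2.0
        np.testing.assert_allclose(J, expect, atol=1e-12)

    def test_point_and_voxel_routes_agree_on_smooth_field(self):
        field = make_rigid_rotation(omega=5.0)
        J_vox = velocity_jacobian(field, 0, voxel=(4, 4, 4))
        J_pt = velocity_jacobian(field, 0, p=np.zeros(3))
        np.testing.assert_allclose(J_pt, J_vox, atol=1e-10)

    def test_exactly_one_location_required(self):
        field = make_uniform()
        with pytest.raises(ValueError, match="exactly one"):
            velocity_jacobian(field, 0)


class TestLambda2Values:
    def test_rigid_rotation_minus_omega_squared(self):
        lam = lambda2_at(np.array([[0.0, -5.0, 0.0], [5.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        assert lam.l1 == pytest.approx(-25.0)
        assert lam.l2 == pytest.approx(-25.0)
        assert lam.l3 == pytest.approx(0.0, abs=1e-9)
        assert lam.l1 <= lam.l2 <= lam.l3

    def test_planar_shear_zero(self):
        lam = lambda2_at(np.array([[0.0, 3.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        assert lam.l2 == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lambda2_at(np.full((3, 3), np.nan))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_any_unidirectional_flow_has_zero_lambda2(self, seed):
        """v = (0, 0, w(x, y)) gives S^2 + W^2 = 0 identically."""
        rng = np.random.default_rng(seed)
        gx, gy = rng.normal(0, 50, 2)
        J = np.zeros((3, 3))
        J[2, 0], J[2, 1] = gx, gy
        lam = lambda2_at(J)
        scale = max(1.0, gx * gx + gy * gy)
        assert abs(lam.l2) < 1e-10 * scale


class TestLambda2Field:
    def test_poiseuille_tube_zero_everywhere(self):
        # pure axial parabolic flow: unidirectional => lambda2 == 0
        spec = canonical_spec(spacing=1.0)
        spec = type(spec)(R=spec.R, vm=spec.vm, gamma=0.0, rc=spec.rc, l=spec.l,
                          bounds=spec.bounds, spacing=1.0)
        field = build_phantom_field(spec)
        l2 = vf.lambda2_field(field, 0)
        assert np.abs(l2.values[l2.valid]).max() < 1e-9

    def test_rigid_rotation_lattice(self):
        field = make_rigid_rotation(omega=5.0)
        l2 = vf.lambda2_field(field, 0)
        np.testing.assert_allclose(l2.values[l2.valid], -25.0, rtol=1e-6)

    def test_phantom_negative_core_positive_far_field(self, canonical_field_1mm):
        """lambda2 < 0 in a tube around the vortex axis; the analytic
        Jacobian gives lambda2 >= 0 beyond ~3 core radii."""
        spec = canonical_spec()
        field = canonical_field_1mm
        l2 = vf.lambda2_field(field, 0)
        xs = [field.origin[a] + field.spacing[a] * np.arange(field.spatial_shape[a])
              for a in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        R = np.hypot(X, Y)
        near_axis = l2.valid & (R < spec.rc) & (np.abs(Z) < 0.5 * spec.l)
        assert (l2.values[near_axis] < 0).all()
        # analytic route far from the core: central difference of the closed
        # form with a tiny step (truncation ~1e-8 of the local scale)
        probe = [(r, 0.0, z) for r in (3.2 * spec.rc, 5.0, 8.0) for z in (0.0, 20.0)]
        h = 1e-4
        for p in probe:
            J = np.zeros((3, 3))
            for b in range(3):
                e = np.zeros(3)
                e[b] = h
                J[:, b] = (analytic_velocity(spec, np.add(p, e))
                           - analytic_velocity(spec, np.subtract(p, e))) / (2 * h)
            assert lambda2_at(J).l2 >= -1e-6

    def test_scheme_restricted_to_difference_stencils(self, canonical_field_1mm):
        with pytest.raises(ValueError, match="scheme"):
            jacobian_lattice(canonical_field_1mm, 0, "circ8")


class TestInvariances:
    def test_galilean_bit_identical(self):
        rng = np.random.default_rng(11)
        comps = [rng.integers(-1000, 1000, (1, 8, 8, 8)).astype(float) for _ in range(3)]
        field = vf.VelocityField4D(*comps, spacing=1.0)
        shifted = vf.VelocityField4D(*(c + o for c, o in zip(comps, (64.0, -128.0, 256.0))),
                                     spacing=1.0)
        a = vf.lambda2_field(field, 0)
        b = vf.lambda2_field(shifted, 0)
        np.testing.assert_array_equal(a.values[a.valid], b.values[b.valid])

    def test_rotation_equivariance_on_quadratic_field(self):
        """Rotating a (quadratic) velocity field and the frame leaves lambda2
        unchanged: lambda2_R(R p) == lambda2(p).  Quadratic fields make both
        the stencil and the interpolant exact, isolating the algebra."""
        rng = np.random.default_rng(2)
        L = rng.normal(0, 1, (3, 3))
        Q = rng.normal(0, 0.1, (3, 3, 3))

        def vel(P):
            lin = np.einsum("ab,...b->...a", L, P)
            quad = np.einsum("abc,...b,...c->...a", Q, P, P)
            return lin + quad

        Rm = Rotation.from_euler("zyx", [33.0, -17.0, 58.0], degrees=True).as_matrix()

        def vel_rot(P):
            return np.einsum("ab,...b->...a", Rm, vel(np.einsum("ba,...b->...a", Rm, P)))

        n, h = 13, 0.5
        xs = h * (np.arange(n) - (n - 1) / 2)
        P = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1)

        def make(fn, scale):
            V = fn(P * 1.0)
            # rotated grid must contain the rotated probes: same cube works
            return vf.VelocityField4D(V[..., 0][None], V[..., 1][None], V[..., 2][None],
                                      spacing=h, origin=(xs[0],) * 3)

        f0 = make(vel, 1.0)
        f1 = make(vel_rot, 1.0)
        probes = rng.uniform(-1.0, 1.0, (20, 3))
        lam0 = lambda2_at_points(f0.sampler(0), probes)
        lam1 = lambda2_at_points(f1.sampler(0), probes @ Rm.T)
        scale = np.maximum(1.0, np.abs(lam0))
        np.testing.assert_allclose(lam1 / scale, lam0 / scale, atol=1e-7)
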