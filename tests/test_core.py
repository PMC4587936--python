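import numpy as np
import pytest

import vortexflow as vf
from vortexflow.core import (
    TrackingParams,
    _FieldProbe,
    core_metrics_timeseries,
    find_seed_points,
    pattern_search_correct,
    radial_cross_section,
    rk4_predict,
    track_core,
)
from vortexflow.lambda2 import lambda2_field
from vortexflow.phantom import analytic_velocity, build_phantom_field, canonical_spec

from conftest import make_rigid_rotation

FAST = TrackingParams(cross_sections=False)


@pytest.fixture(scope="module")
def phantom_1mm():
    field = build_phantom_field(canonical_spec(spacing=1.0))
    return field, lambda2_field(field, 0)


class TestSeeding:
    def test_single_seed_on_phantom_axis(self, phantom_1mm):
        field, l2 = phantom_1mm
        seeds = find_seed_points(l2)
        assert len(seeds) == 1
        # within one voxel of the axis at the taper maximum z = 0
        assert np.linalg.norm(seeds[0]) <= np.sqrt(3.0)

    def test_no_seed_without_vortex(self):
        spec = canonical_spec(spacing=2.0)
        spec = type(spec)(R=spec.R, vm=spec.vm, gamma=0.0, rc=spec.rc, l=spec.l,
                          bounds=spec.bounds, spacing=2.0)
        field = build_phantom_field(spec)
        assert len(find_seed_points(lambda2_field(field, 0))) == 0

    def test_two_separated_vortices_give_two_seeds(self):
        """Two tapered vortices 12 mm apart (> suppression radius) seed twice."""
        spec = canonical_spec(spacing=1.0, R=30.0, vm=0.0,
                              bounds=((-12.0, 12.0), (-7.0, 7.0), (-60.0, 60.0)))
        xs = np.arange(-12.0, 12.5)
        ys = np.arange(-7.0, 7.5)
        zs = np.arange(-60.0, 60.5)
        P = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        v = (analytic_velocity(spec, P - [-6.0, 0, 0])
             + analytic_velocity(spec, P - [6.0, 0, 0]))
        field = vf.VelocityField4D(v[..., 0][None], v[..., 1][None], v[..., 2][None],
                                   spacing=1.0, origin=(xs[0], ys[0], zs[0]))
        seeds = find_seed_points(lambda2_field(field, 0), suppression_radius=5.0)
        assert len(seeds) == 2
        assert {round(s[0]) for s in seeds} == {-6, 6}

    def test_suppression_merges_close_seeds(self, phantom_1mm):
        field, l2 = phantom_1mm
        # huge suppression radius can never yield more than one seed
        assert len(find_seed_points(l2, suppression_radius=1000.0)) == 1


class TestPredictor:
    def test_step_from_axis_stays_on_axis(self, phantom_1mm):
        field, _ = phantom_1mm
        probe = _FieldProbe(field, 0)
        p, status = rk4_predict(probe, np.zeros(3), +1, 0.5)
        assert status == "ok"
        assert np.hypot(p[0], p[1]) < 1e-3
        assert p[2] == pytest.approx(0.5, abs=1e-6)

    def test_rigid_rotation_trajectory_is_straight(self):
        field = make_rigid_rotation(omega=5.0, n=11)
        probe = _FieldProbe(field, 0)
        p = np.zeros(3)
        for _ in range(4):
            p, status = rk4_predict(probe, p, +1, 0.5)
            assert status == "ok"
        np.testing.assert_allclose(p, [0, 0, 2.0], atol=1e-9)

    def test_zero_vorticity_stalls(self):
        shape = (1, 8, 8, 8)
        field = vf.VelocityField4D(np.zeros(shape), np.zeros(shape),
                                   np.full(shape, 100.0), spacing=1.0)
        probe = _FieldProbe(field, 0)
        p0 = np.array([3.5, 3.5, 3.5])
        p, status = rk4_predict(probe, p0, +1, 0.5)
        assert status == "stalled"
        np.testing.assert_array_equal(p, p0)


class TestCorrector:
    def test_quadratic_bowl_converges_to_minimum(self):
        a, b = 0.31, -0.42

        def objective(pts):
            return (pts[:, 0] - a) ** 2 + (pts[:, 1] - b) ** 2

        p, status = pattern_search_correct(objective, np.zeros(3), (0, 0, 1.0),
                                           mesh0=0.5, tol=1e-4, search_radius=2.0)
        assert status == "ok"
        assert np.hypot(p[0] - a, p[1] - b) < 1e-3

    def test_fixed_point_returns_start(self):
        def objective(pts):
            return pts[:, 0] ** 2 + pts[:, 1] ** 2

        p, _ = pattern_search_correct(objective, np.zeros(3), (0, 0, 1.0),
                                      mesh0=0.25, tol=0.01, search_radius=2.0)
        np.testing.assert_array_equal(p, np.zeros(3))

    def test_search_confined_to_radius(self):
        # minimum far outside the confinement disc must not be reached
        def objective(pts):
            return (pts[:, 0] - 10.0) ** 2 + pts[:, 1] ** 2

        p, _ = pattern_search_correct(objective, np.zeros(3), (0, 0, 1.0),
                                      mesh0=0.5, tol=1e-3, search_radius=1.5)
        assert np.linalg.norm(p) <= 1.5 + 1e-9

    def test_off_axis_point_recentred_on_phantom(self, phantom_1mm):
        field, _ = phantom_1mm
        probe = _FieldProbe(field, 0)
        start = np.array([0.5, 0.0, 0.0])
        p, status = pattern_search_correct(probe.lambda2, start, (0, 0, 1.0),
                                           mesh0=0.5, tol=0.01, search_radius=2.0)
        assert status == "ok"
        assert np.hypot(p[0], p[1]) < 0.05


class TestCrossSection:
    def test_phantom_axis_radius(self, phantom_1mm):
        field, _ = phantom_1mm
        spec = canonical_spec()
        vort = vf.curl_central2(field, 0)
        r, area, trunc = radial_cross_section(vort, np.zeros(3), (0, 0, 1.0),
                                              ray_threshold=150.0)
        # threshold crossing of the Gaussian profile survives 1 mm sampling well
        expect = spec.rc * np.sqrt(np.log(397.9 / 150.0))
        assert r == pytest.approx(expect, rel=0.05)
        assert area == pytest.approx(np.pi * r * r)
        assert not trunc

    def test_below_threshold_reports_zero(self, phantom_1mm):
        field, _ = phantom_1mm
        vort = vf.curl_central2(field, 0)
        r, area, trunc = radial_cross_section(vort, (0.0, 0.0, 45.0), (0, 0, 1.0),
                                              ray_threshold=150.0)
        assert (r, area, trunc) == (0.0, 0.0, False)

    def test_rays_truncated_at_mask_boundary(self):
        # rigid rotation with 2*Omega above threshold everywhere in the box
        field = make_rigid_rotation(omega=100.0, n=11)
        vort = vf.curl_central2(field, 0)
        r, area, trunc = radial_cross_section(vort, np.zeros(3), (0, 0, 1.0),
                                              ray_threshold=150.0, max_radius=30.0)
        assert trunc


class TestTracking:
    def test_core_follows_phantom_axis(self, phantom_1mm):
        field, l2 = phantom_1mm
        seeds = find_seed_points(l2)
        core = track_core(field, 0, seeds[0], FAST)
        rms = np.sqrt(np.mean(core.points[:, 0] ** 2 + core.points[:, 1] ** 2))
        assert rms <= 1.0  # within one voxel at 1 mm
        assert core.length() == pytest.approx(76.9, rel=0.03)
        assert (core.lam2 < 0).all()
        assert core.stop_reason_start == core.stop_reason_end == "weak_vorticity"
        # consecutive spacing bounded by twice the step size
        steps = np.linalg.norm(np.diff(core.points, axis=0), axis=1)
        assert steps.max() <= 2 * FAST.step_mm(field.spacing)

    def test_tracking_deterministic_bit_identical(self, phantom_1mm):
        field, l2 = phantom_1mm
        seeds = find_seed_points(l2)
        a = track_core(field, 0, seeds[0], FAST)
        b = track_core(field, 0, seeds[0], FAST)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.omega_mag, b.omega_mag)

    def test_seed_in_irrotational_field_degenerates(self):
        shape = (1, 8, 8, 8)
        field = vf.VelocityField4D(np.zeros(shape), np.zeros(shape),
                                   np.full(shape, 100.0), spacing=1.0)
        core = track_core(field, 0, np.array([3.5, 3.5, 3.5]), FAST)
        assert len(core.points) == 1
        assert core.length() == 0.0

    def test_single_perturbed_voxel_self_corrects(self, phantom_1mm):
        """A 10% single-voxel velocity error mid-core moves the recovered
        axis by far less than one voxel."""
        field, l2 = phantom_1mm
        seeds = find_seed_points(l2)
        base = track_core(field, 0, seeds[0], FAST)
        pert = build_phantom_field(canonical_spec(spacing=1.0))
        ix = int(round(-pert.origin[0]))
        iz = int(round(15.0 - pert.origin[2]))
        for comp in (pert.vx, pert.vy, pert.vz):
            comp[0, ix + 1, ix, iz] *= 1.10
        noisy = track_core(pert, 0, find_seed_points(lambda2_field(pert, 0))[0], FAST)

        def rms(c):
            return np.sqrt(np.mean(c.points[:, 0] ** 2 + c.points[:, 1] ** 2))

        assert abs(rms(noisy) - rms(base)) < 1.0

    def test_polyline_export(self, phantom_1mm, tmp_path):
        field, l2 = phantom_1mm
        core = track_core(field, 0, find_seed_points(l2)[0], FAST)
        csv = core.write_csv(str(tmp_path / "core.csv"))
        vtk = core.write_vtk(str(tmp_path / "core.vtk"))
        import pandas as pd

        frame = pd.read_csv(csv)
        assert len(frame) == len(core.points)
        head = open(vtk).read().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any(line.startswith("LINES") for line in head)


class TestMetricsTimeseries:
    def test_static_phantom_metrics_identical_per_phase(self):
        field = build_phantom_field(canonical_spec(spacing=1.0), nt=2)
        m = core_metrics_timeseries(field, FAST)
        assert m.length[0] == pytest.approx(m.length[1])
        assert m.mean_vorticity[0] == pytest.approx(m.mean_vorticity[1])
        assert m.length[0] == pytest.approx(76.9, rel=0.03)
        # along-core mean of the tapered profile
        assert m.mean_vorticity[0] == pytest.approx(253.5, rel=0.07)
        assert m.min_vorticity[0] <= m.mean_vorticity[0] <= m.max_vorticity[0]

    def test_no_vortex_reports_zeros(self):
        spec = canonical_spec(spacing=2.0)
        spec = type(spec)(R=spec.R, vm=spec.vm, gamma=0.0, rc=spec.rc, l=spec.l,
                          bounds=spec.bounds, spacing=2.0)
        field = build_phantom_field(spec, nt=2)
        m = core_metrics_timeseries(field, FAST)
        for arr in (m.length, m.min_vorticity, m.max_vorticity, m.mean_vorticity,
                    m.max_area):
            np.testing.assert_array_equal(arr, 0.0)
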