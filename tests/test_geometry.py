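"""Geometric measurement operators: closed-form cases and invariances."""

import numpy as np
import pytest

from bonylabyrinth import geometry as ge
from conftest import random_rotation


def circle(radius=1.0, n=256, tilt_deg=0.0, noise_sd=0.0, rng=None):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
    if tilt_deg:
        a = np.radians(tilt_deg)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        pts = pts @ rot.T
    if noise_sd:
        pts = pts + rng.normal(0, noise_sd, pts.shape)
    return ge.Centerline(pts, closed=True)


class TestPlaneFit:
    def test_flat_points_recovered_exactly(self):
        line = circle()
        fit = ge.fit_plane(line)
        assert abs(fit.normal[2]) == pytest.approx(1.0)
        assert fit.rms_residual_mm == pytest.approx(0.0, abs=1e-12)

    def test_tilted_circle_normal_recovered(self):
        fit = ge.fit_plane(circle(tilt_deg=30.0))
        truth = np.array([0, -np.sin(np.radians(30)), np.cos(np.radians(30))])
        angle = np.arccos(np.clip(abs(fit.normal @ truth), -1, 1))
        assert angle < 1e-6

    def test_noise_floor_reported(self, rng):
        fit = ge.fit_plane(circle(n=2000, noise_sd=0.01, rng=rng))
        assert fit.rms_residual_mm == pytest.approx(0.01, rel=0.3)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 16), np.zeros(16), np.zeros(16)])
        with pytest.raises(ValueError, match="collinear"):
            ge.fit_plane(ge.Centerline(pts))

    def test_residual_zero_iff_coplanar(self, rng):
        flat = circle()
        assert ge.fit_plane(flat).rms_residual_mm < 1e-9
        warped = flat.points.copy()
        warped[:, 2] += 0.05 * np.sin(3 * np.linspace(0, 2 * np.pi, len(warped)))
        assert ge.fit_plane(ge.Centerline(warped)).rms_residual_mm > 1e-9


class TestArcExtents:
    def test_unit_circle(self):
        line = circle()
        h, w = ge.arc_extents(line, ge.fit_plane(line))
        assert (h, w) == pytest.approx((2.0, 2.0), abs=1e-3)

    def test_ellipse_extents_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        pts = np.column_stack([1.0 * np.cos(t), 0.8 * np.sin(t), np.zeros_like(t)])
        line = ge.Centerline(pts)
        h, w = ge.arc_extents(line, ge.fit_plane(line))
        assert h == pytest.approx(1.6, abs=1e-3)
        assert w == pytest.approx(2.0, abs=1e-3)


class TestLinearDeviation:
    def test_planar_curve_is_zero(self):
        line = circle()
        assert ge.linear_deviation(line, ge.fit_plane(line)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_warp_measures_twice_amplitude(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.1 * np.sin(2 * t)])
        line = ge.Centerline(pts)
        assert ge.linear_deviation(line, ge.fit_plane(line)) == pytest.approx(0.2, rel=0.02)

    def test_one_sided_bump(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        bump = 0.2 * np.exp(-(((t - np.pi) / 0.3) ** 2))
        pts = np.column_stack([np.cos(t), np.sin(t), bump])
        line = ge.Centerline(pts)
        got = ge.linear_deviation(line, ge.fit_plane(line))
        # close to the bump height; the total-least-squares plane tilts a
        # few percent into a one-sided feature
        assert 0.2 * 0.90 <= got <= 0.2 * 1.1


class TestInterplaneAngle:
    @staticmethod
    def plane(normal, centroid=(0, 0, 0)):
        n = np.asarray(normal, float)
        return ge.PlaneFit(n / np.linalg.norm(n), np.asarray(centroid, float), 0.0)

    def test_orthogonal_planes(self):
        a = self.plane((0, 0, 1))
        b = self.plane((1, 0, 0))
        assert ge.interplane_angle(a, b, (1, 1, 1)) == pytest.approx(90.0)

    def test_identical_planes(self):
        a = self.plane((0, 0, 1), centroid=(0, 0, -1))
        b = self.plane((0, 0, -1), centroid=(0, 0, -1))
        # both normals are re-oriented toward the reference point: angle 0
        assert ge.interplane_angle(a, b, (0, 0, 5)) == pytest.approx(0.0)

    def test_obtuse_angle_preserved_by_orientation(self):
        ang = np.radians(109.0)
        ref = np.zeros(3)
        a = self.plane((0, 0, 1), centroid=(0, 0, -2))
        b = self.plane((np.sin(ang), 0, np.cos(ang)),
                       centroid=-2 * np.array([np.sin(ang), 0, np.cos(ang)]))
        assert ge.interplane_angle(a, b, ref) == pytest.approx(109.0)


class TestCochlearOps:
    def test_full_planar_circle_coils_360(self):
        line = circle(n=257)
        # re-create with endpoint to complete the loop exactly
        t = np.linspace(0, 2 * np.pi, 257)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        got = ge.cochlear_coiling(ge.Centerline(pts), (0, 0, 0), (0, 0, 1))
        assert got == pytest.approx(360.0, abs=1e-9)

    def test_reversed_order_same_magnitude(self):
        t = np.linspace(0, np.radians(700), 512)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.001 * t])
        fwd = ge.cochlear_coiling(ge.Centerline(pts), (0, 0, 0), (0, 0, 1))
        rev = ge.cochlear_coiling(ge.Centerline(pts[::-1]), (0, 0, 0), (0, 0, 1))
        assert fwd == pytest.approx(rev)
        assert fwd == pytest.approx(700.0, abs=1e-6)

    def test_point_on_axis_rejected(self):
        pts = np.zeros((16, 3))
        pts[:, 2] = np.arange(16)
        pts[1:, 0] = 1.0
        with pytest.raises(ValueError, match="axis"):
            ge.cochlear_coiling(ge.Centerline(pts), (0, 0, 0), (0, 0, 1))

    def test_flat_spiral_aspect_zero(self):
        t = np.linspace(0, 2 * np.pi * 1.5, 256)
        r = 1.0 - 0.05 * t
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)])
        h, w, aspect, full = ge.cochlear_profile(
            ge.Centerline(pts), (0, 0, 0), (0, 0, 1)
        )
        assert h == pytest.approx(0.0, abs=1e-12)
        assert aspect == pytest.approx(0.0, abs=1e-12)
        assert full

    def test_profile_scale_invariance(self):
        t = np.linspace(0, np.radians(800), 512)
        r = 1.0 - 0.03 * t
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), 0.002 * t * 180 / np.pi])
        line = ge.Centerline(pts)
        _, _, aspect, _ = ge.cochlear_profile(line, (0, 0, 0), (0, 0, 1))
        scaled = ge.Centerline(pts * 3.7)
        _, _, aspect2, _ = ge.cochlear_profile(scaled, (0, 0, 0), (0, 0, 1))
        assert aspect == pytest.approx(aspect2, rel=1e-12)

    def test_partial_turn_flagged(self):
        t = np.linspace(0, np.pi, 64)  # half a turn only
        pts = np.column_stack([np.cos(t), np.sin(t), 0.01 * t])
        *_, full = ge.cochlear_profile(ge.Centerline(pts), (0, 0, 0), (0, 0, 1))
        assert not full


class TestSagittalIndex:
    @staticmethod
    def arc(center_z):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack([np.cos(t), np.zeros_like(t) + 2.0, np.sin(t) + center_z])
        return ge.Centerline(pts)

    @staticmethod
    def lateral_plane():
        return ge.PlaneFit(np.array([0.0, 0.0, 1.0]), np.zeros(3), 0.0)

    def test_arc_entirely_above_plane(self):
        got = ge.sagittal_index(self.arc(center_z=2.0), self.lateral_plane(), (0, 0, 1))
        assert got == 0.0

    def test_plane_through_midpoint_gives_50(self):
        got = ge.sagittal_index(self.arc(center_z=0.0), self.lateral_plane(), (0, 0, 1))
        assert got == pytest.approx(50.0, abs=1.0)

    def test_30_percent_below(self):
        # arc spans z in [c-1, c+1]; 30% below 0 puts the centre at +0.4
        got = ge.sagittal_index(self.arc(center_z=0.4), self.lateral_plane(), (0, 0, 1))
        assert got == pytest.approx(30.0, abs=1.0)

    def test_arc_entirely_below_gives_100(self):
        got = ge.sagittal_index(self.arc(center_z=-2.0), self.lateral_plane(), (0, 0, 1))
        assert got == 100.0


class TestRigidInvariance:
    def test_measurements_invariant_under_rigid_motion(self, rng):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack(
            [1.3 * np.cos(t), 0.9 * np.sin(t), 0.08 * np.sin(2 * t)]
        )
        line = ge.Centerline(pts)
        fit = ge.fit_plane(line)
        h, w = ge.arc_extents(line, fit)
        dev = ge.linear_deviation(line, fit)
        for _ in range(5):
            rot = random_rotation(rng)
            shift = rng.normal(0, 10, 3)
            moved = ge.Centerline(pts @ rot.T + shift)
            mfit = ge.fit_plane(moved)
            mh, mw = ge.arc_extents(moved, mfit)
            assert (mh, mw) == pytest.approx((h, w), rel=1e-9)
            assert ge.linear_deviation(moved, mfit) == pytest.approx(dev, rel=1e-9)
            assert mfit.rms_residual_mm == pytest.approx(fit.rms_residual_mm, rel=1e-9)

    def test_lengths_scale_linearly_angles_invariant(self):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        pts = np.column_stack([np.cos(t), 0.8 * np.sin(t), 0.05 * np.sin(3 * t)])
        line = ge.Centerline(pts)
        fit = ge.fit_plane(line)
        h, w = ge.arc_extents(line, fit)
        dev = ge.linear_deviation(line, fit)
        k = 4.25
        scaled = ge.Centerline(pts * k)
        sfit = ge.fit_plane(scaled)
        sh, sw = ge.arc_extents(scaled, sfit)
        assert (sh, sw) == pytest.approx((k * h, k * w), rel=1e-9)
        assert ge.linear_deviation(scaled, sfit) == pytest.approx(k * dev, rel=1e-9)
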