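import numpy as np
import pytest

from fevarsim import (
    Centerline,
    MorphoMetrics,
    branching_angle,
    breathing_deltas,
    end_stent_angle,
    menger_curvature,
    pointwise_curvature,
)
from fevarsim.errors import InvalidPairingError
from fevarsim.stents import DeployedSG, StentGraftSpec

from conftest import random_rotation


def circle(radius, n=200, plane="xy"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)])
    return Centerline(pts)


def straight(n=41, length=40.0):
    return Centerline(
        np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)])
    )


def kinked_branch(kink_deg, s_kink=20.0, total=35.0):
    th = np.radians(kink_deg)
    s1 = np.arange(0.0, s_kink + 1)
    seg1 = np.column_stack([s1, np.zeros_like(s1), np.zeros_like(s1)])
    d = np.array([np.cos(th), np.sin(th), 0.0])
    s2 = np.arange(1.0, total - s_kink + 1)
    seg2 = seg1[-1] + s2[:, None] * d[None, :]
    return Centerline(np.vstack([seg1, seg2]))


SPEC = StentGraftSpec("Patient 1", "RRA", "nominal", 23.0, 7.0)


class TestCurvature:
    def test_circle_curvature_exact(self):
        # points exactly on the circle at ~1 mm arc spacing: the
        # circumcircle of every cocircular triple is the circle itself
        prof, kmax = pointwise_curvature(circle(10.0, n=63))
        np.testing.assert_allclose(prof, 0.1, atol=1e-12)
        assert kmax == pytest.approx(0.1, abs=1e-12)

    def test_straight_line_zero(self):
        prof, kmax = pointwise_curvature(straight())
        assert np.all(prof == 0.0) and kmax == 0.0

    def test_helix_matches_analytic(self):
        r, c = 10.0, 5.0
        t = np.linspace(0, 4 * np.pi, 2000)
        helix = Centerline(np.column_stack([r * np.cos(t), r * np.sin(t), c * t]))
        prof, kmax = pointwise_curvature(helix.resample(1.0))
        assert kmax == pytest.approx(r / (r**2 + c**2), rel=0.01)

    def test_matches_brute_force_circumradius_exactly(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(30, 3)), axis=0)
        cl = Centerline(pts)
        prof, _ = pointwise_curvature(cl)
        for i in range(1, len(pts) - 1):
            # independent circumradius formula: R = abc / 4A
            a = np.linalg.norm(pts[i] - pts[i - 1])
            b = np.linalg.norm(pts[i + 1] - pts[i])
            c = np.linalg.norm(pts[i + 1] - pts[i - 1])
            area = 0.5 * np.linalg.norm(np.cross(pts[i] - pts[i - 1], pts[i + 1] - pts[i - 1]))
            assert prof[i - 1] == pytest.approx(4 * area / (a * b * c), rel=1e-13)
            assert prof[i - 1] == pytest.approx(
                menger_curvature(pts[i - 1], pts[i], pts[i + 1]), rel=1e-13
            )

    def test_collinear_triple_is_zero_not_error(self):
        assert menger_curvature(
            np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])
        ) == 0.0


class TestBranchingAngle:
    def test_perpendicular_branch(self, straight_aorta, straight_branch):
        assert branching_angle(straight_aorta, straight_branch) == pytest.approx(90.0, abs=1.0)

    def test_near_parallel_branch_small_angle(self, straight_aorta):
        # branch running along the aorta direction (caudal)
        start = straight_aorta.point_at(100.0) + np.array([10.0, 0, 0])
        d = straight_aorta.tangent_at(100.0)
        pts = start[None, :] + np.arange(40.0)[:, None] * d[None, :]
        assert branching_angle(straight_aorta, Centerline(pts)) < 5.0

    def test_short_branch_shrinks_window_with_warning(self, straight_aorta):
        start = straight_aorta.point_at(100.0) + np.array([10.0, 0, 0])
        pts = start[None, :] + np.arange(4.0)[:, None] * np.array([[1.0, 0, 0]])
        with pytest.warns(UserWarning, match="shrink"):
            branching_angle(straight_aorta, Centerline(pts), fit_window_mm=5.0)


class TestEndStentAngle:
    def test_straight_artery_zero(self):
        branch = straight(41, 40.0)
        sg = DeployedSG(SPEC, branch, -3.0, 20.0, 8.0)
        assert end_stent_angle(branch, sg) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_kink_recovered(self):
        branch = kinked_branch(20.0, s_kink=20.0)
        sg = DeployedSG(SPEC, branch, -3.0, 20.0, 8.0)
        assert end_stent_angle(branch, sg) == pytest.approx(20.0, abs=1.0)

    def test_unavailable_when_stent_reaches_distal_end(self):
        branch = straight(41, 40.0)
        sg = DeployedSG(SPEC, branch, -3.0, 20.0, 8.0)
        short = Centerline(branch.points[:22])  # ends 1 mm past the stent
        assert end_stent_angle(short, sg) is None


class TestDeltas:
    def _metrics(self, ba, kmax, esa=None, **labels):
        return MorphoMetrics(ba, kmax, np.array([kmax]), esa, **labels)

    def test_identical_inputs_zero(self):
        m = self._metrics(80.0, 0.05, 3.0)
        d = breathing_deltas(m, self._metrics(80.0, 0.05, 3.0))
        assert d.d_branching_angle_deg == 0.0
        assert d.d_end_stent_angle_deg == 0.0
        assert d.d_max_curvature_per_mm == 0.0

    def test_absolute_difference(self):
        d = breathing_deltas(self._metrics(80.0, 0.05), self._metrics(71.0, 0.02))
        assert d.d_branching_angle_deg == pytest.approx(9.0)
        assert d.d_max_curvature_per_mm == pytest.approx(0.03)

    def test_mismatched_configurations_rejected(self):
        a = self._metrics(80.0, 0.05, patient="P1", artery="RRA")
        b = self._metrics(71.0, 0.05, patient="P1", artery="LRA")
        with pytest.raises(InvalidPairingError):
            breathing_deltas(a, b)


class TestGeometricInvariance:
    def test_rigid_motion_leaves_metrics_unchanged(
        self, straight_aorta, straight_branch, rng
    ):
        branch = kinked_branch(15.0)
        sg = DeployedSG(SPEC, branch, -3.0, 20.0, 8.0)
        ba0 = branching_angle(straight_aorta, straight_branch)
        esa0 = end_stent_angle(branch, sg)
        _, k0 = pointwise_curvature(branch.resample(1.0))
        R = random_rotation(rng)
        t = np.array([12.0, -4.0, 9.0])
        aorta_r = Centerline(straight_aorta.points @ R.T + t)
        branch90_r = Centerline(straight_branch.points @ R.T + t)
        branch_r = Centerline(branch.points @ R.T + t)
        sg_r = DeployedSG(SPEC, branch_r, -3.0, 20.0, 8.0)
        assert abs(branching_angle(aorta_r, branch90_r) - ba0) < 1e-9
        assert abs(end_stent_angle(branch_r, sg_r) - esa0) < 1e-9
        _, k1 = pointwise_curvature(branch_r.resample(1.0))
        assert abs(k1 - k0) < 1e-9

    def test_curvature_scales_inversely_angles_invariant(self, straight_aorta, straight_branch):
        s = 2.5
        branch = kinked_branch(15.0)
        _, k0 = pointwise_curvature(branch.resample(1.0))
        scaled = Centerline(branch.points * s)
        _, k1 = pointwise_curvature(scaled.resample(1.0 * s))
        assert k1 == pytest.approx(k0 / s, rel=1e-9)
        a0 = branching_angle(straight_aorta, straight_branch)
        a1 = branching_angle(
            Centerline(straight_aorta.points * s), Centerline(straight_branch.points * s)
        )
        assert a1 == pytest.approx(a0, abs=1e-9)
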