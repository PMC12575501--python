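import numpy as np
import pytest

from fevarsim import (
    Centerline,
    MaterialProperties,
    StrutCrossSection,
    build_rod,
    catalog_lookup,
    deploy_geometric,
    effective_bending_rigidity,
    simulate_breathing,
    solve_equilibrium,
)
from fevarsim.errors import InvalidInputError
from fevarsim.morpho import branching_angle
from fevarsim.rod import RodModel, _energy_grad, _fd_hessian, _hessian
from fevarsim.synthetic import generate_patient

from conftest import random_rotation


def straight_line(length, n):
    return Centerline(np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, length, n)]))


class TestBuildRod:
    def test_uniform_discretization(self):
        rod = build_rod(straight_line(40.0, 81))
        assert rod.n_nodes == 41
        np.testing.assert_allclose(rod.rest_lengths, 1.0)
        assert np.all(rod.bend_rigidity == rod.bend_rigidity[0])

    def test_stented_interval_elevated(self):
        branch = straight_line(40.0, 81)
        spec = catalog_lookup("Patient 1", "RRA", "nominal")  # 23 x 7
        sg = deploy_geometric(branch, spec, 4.0, 8.0)  # in-artery [0, 19]
        rod = build_rod(branch, artery_rigidity=100.0, deployed_sg=sg, rigidity_ratio=50.0)
        s = rod.arc_lengths[1:-1]
        inside = s <= 19.0 + 1e-9
        assert np.all(rod.bend_rigidity[inside] == 5000.0)
        assert np.all(rod.bend_rigidity[~inside] == 100.0)

    def test_catalog_rigidity_ratio_far_above_one(self):
        spec = catalog_lookup("Patient 1", "RRA", "nominal")
        total = effective_bending_rigidity(
            MaterialProperties(), StrutCrossSection(), spec, 6, 100.0
        )
        assert total / 100.0 > 100.0

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            build_rod(straight_line(5.0, 11))


class TestEnergyModel:
    def test_gradient_matches_finite_differences(self, rng):
        rod = build_rod(straight_line(20.0, 41))
        P = rod.rest_points + 0.2 * rng.normal(size=rod.rest_points.shape)
        E0, G = _energy_grad(rod, P)
        eps = 1e-7
        for i, j in [(3, 0), (10, 1), (19, 2)]:
            Pp, Pm = P.copy(), P.copy()
            Pp[i, j] += eps
            Pm[i, j] -= eps
            fd = (_energy_grad(rod, Pp)[0] - _energy_grad(rod, Pm)[0]) / (2 * eps)
            assert G[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-4)

    def test_analytic_hessian_matches_fd(self, rng):
        rod = build_rod(straight_line(15.0, 31))
        rest = rod.rest_points
        free = np.arange(2, rod.n_nodes - 1)
        fc = (free[:, None] * 3 + np.arange(3)).ravel()
        tail = rest[-1] + np.array([0.5, 0.2, 1.0])

        def fun(x):
            Q = rest.copy()
            Q[-1] = tail
            Q[free] = x.reshape(-1, 3)
            E, G = _energy_grad(rod, Q)
            return E, G[free].ravel()

        x = (rest[free] + 0.1 * rng.normal(size=(len(free), 3))).ravel()
        _, g = fun(x)
        Q = rest.copy()
        Q[-1] = tail
        Q[free] = x.reshape(-1, 3)
        Ha = _hessian(rod, Q)[np.ix_(fc, fc)]
        Hf = _fd_hessian(fun, x, g)
        assert np.abs(Ha - Hf).max() < 1e-3 * max(1.0, np.abs(Hf).max())


class TestEquilibrium:
    def test_zero_displacement_returns_rest_exactly(self):
        rod = build_rod(straight_line(40.0, 81))
        sol = solve_equilibrium(rod, np.zeros(3))
        np.testing.assert_array_equal(sol.positions, rod.rest_points)
        assert sol.energy == 0.0 and sol.converged

    def test_boundary_conditions_satisfied(self, patient):
        branch = patient.renal_right
        rod = build_rod(branch)
        bv = patient.breathing.displacements["right"]
        sol = solve_equilibrium(rod, bv)
        assert sol.converged and sol.grad_norm < 1e-8
        np.testing.assert_allclose(sol.positions[0], rod.rest_points[0], atol=1e-8)
        np.testing.assert_allclose(sol.positions[1], rod.rest_points[1], atol=1e-8)
        np.testing.assert_allclose(sol.positions[-1], rod.rest_points[-1] + bv, atol=1e-8)

    def test_small_deflection_matches_clamped_pinned_beam(self):
        # straight 20-node rod, transverse tip displacement; closed form
        # w(s) = delta (3 s^2 L - s^3) / (2 L^3)
        L, delta = 19.0, 0.2
        rod = build_rod(straight_line(L, 20))
        sol = solve_equilibrium(rod, np.array([delta, 0.0, 0.0]))
        s = np.arange(20.0)
        w_exact = delta * (3 * s**2 * L - s**3) / (2 * L**3)
        assert np.abs(sol.positions[:, 0] - w_exact).max() < 0.02 * delta

    def test_energy_optimal_vs_brute_force_grid(self):
        # 5-node planar rod: solver energy must not exceed any configuration
        # on a 0.05 mm grid over the two free nodes' in-plane coordinates
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        rod = RodModel(pts, np.ones(4), 1e4, np.full(3, 100.0))
        sol = solve_equilibrium(rod, np.array([0.3, 0.0, 0.1]))
        offsets = np.arange(-0.3, 0.3001, 0.05)
        best = np.inf
        base = sol.positions
        for dx2 in offsets:
            for dz2 in offsets:
                for dx3 in offsets:
                    for dz3 in offsets:
                        P = base.copy()
                        P[2, 0] += dx2
                        P[2, 2] += dz2
                        P[3, 0] += dx3
                        P[3, 2] += dz3
                        E, _ = _energy_grad(rod, P)
                        best = min(best, E)
        assert sol.energy <= best + 1e-9

    def test_frame_objectivity(self, rng):
        branch = straight_line(30.0, 61)
        rod = build_rod(branch)
        bv = np.array([1.0, 0.5, 2.0])
        sol = solve_equilibrium(rod, bv)
        R = random_rotation(rng)
        t = np.array([3.0, -7.0, 11.0])
        rod_rot = build_rod(Centerline(branch.points @ R.T + t))
        sol_rot = solve_equilibrium(rod_rot, R @ bv)
        expected = sol.positions @ R.T + t
        assert np.abs(sol_rot.positions - expected).max() < 1e-8


class TestStiffeningEffect:
    def test_branching_delta_non_increasing_in_rigidity_ratio(self, patient):
        branch = patient.renal_left
        spec = catalog_lookup("Patient 1", "LRA", "nominal")
        sg = deploy_geometric(branch, spec, 3.9, spec.diameter_mm + 1)
        bv = patient.breathing.displacements["left"]
        deltas = []
        rest_angle = None
        for ratio in (1.0, 10.0, 100.0):
            rod = build_rod(branch, deployed_sg=sg, rigidity_ratio=ratio)
            sol = solve_equilibrium(rod, bv)
            if rest_angle is None:
                rest_angle = branching_angle(
                    patient.aorta, Centerline(rod.rest_points), fit_window_mm=20.0
                )
            expi_angle = branching_angle(
                patient.aorta, Centerline(sol.positions), fit_window_mm=20.0
            )
            deltas.append(abs(expi_angle - rest_angle))
        assert deltas[0] >= deltas[1] >= deltas[2]


class TestSimulateBreathing:
    def test_zero_bc_identity(self, patient):
        from fevarsim.synthetic import BreathingBC

        bc = BreathingBC(displacements={"left": np.zeros(3), "right": np.zeros(3)})
        insp, expi = simulate_breathing(patient, None, bc)
        for side in ("left", "right"):
            np.testing.assert_array_equal(insp[side].points, expi[side].points)

    def test_deterministic_rerun(self, patient):
        _, e1 = simulate_breathing(patient, None, patient.breathing)
        _, e2 = simulate_breathing(patient, None, patient.breathing)
        for side in ("left", "right"):
            np.testing.assert_array_equal(e1[side].points, e2[side].points)

    def test_stent_constrains_branch_motion(self, patient):
        """With a nominal device the breathing-induced branching-angle
        change is smaller than without it."""
        _, expi_pre = simulate_breathing(patient, None, patient.breathing)
        spec = catalog_lookup("Patient 1", "RRA", "nominal")
        sg = deploy_geometric(patient.renal_right, spec, 3.9, spec.diameter_mm + 1)
        _, expi_post = simulate_breathing(patient, {"right": sg}, patient.breathing)
        rest_angle = branching_angle(patient.aorta, patient.renal_right, fit_window_mm=20.0)
        d_pre = abs(
            branching_angle(patient.aorta, expi_pre["right"], fit_window_mm=20.0) - rest_angle
        )
        d_post = abs(
            branching_angle(patient.aorta, expi_post["right"], fit_window_mm=20.0) - rest_angle
        )
        assert d_post < d_pre
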