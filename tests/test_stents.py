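import numpy as np
import pytest

from fevarsim import (
    Centerline,
    MaterialProperties,
    StentGraftSpec,
    StrutCrossSection,
    catalog_lookup,
    deploy_geometric,
    effective_bending_rigidity,
    sg_catalog,
    three_point_bending_force,
)
from fevarsim.errors import DeploymentInfeasibleError, InvalidConfigError, OutOfValidityError
from fevarsim.stents import catalog_from_csv, catalog_to_csv


def straight_branch(length=40.0):
    n = int(length) + 1
    return Centerline(np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)]))


class TestCatalog:
    def test_twelve_entries(self):
        assert len(sg_catalog()) == 12

    @pytest.mark.parametrize(
        "patient,artery,size_class,length,diameter",
        [
            ("Patient 1", "RRA", "nominal", 23, 7),
            ("Patient 1", "RRA", "shorter", 18, 7),
            ("Patient 1", "RRA", "longer", 27, 7),
            ("Patient 1", "LRA", "nominal", 22, 5),
            ("Patient 2", "RRA", "nominal", 22, 6),
            ("Patient 2", "LRA", "longer", 28, 5),
        ],
    )
    def test_lookup(self, patient, artery, size_class, length, diameter):
        spec = catalog_lookup(patient, artery, size_class)
        assert (spec.length_mm, spec.diameter_mm) == (length, diameter)

    def test_sizes_are_commercial(self):
        for spec in sg_catalog():
            assert spec.length_mm in {18, 22, 23, 27, 28}
            assert spec.diameter_mm in {5, 6, 7}

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "catalog.csv"
        catalog_to_csv(path)
        assert catalog_from_csv(path) == sg_catalog()


class TestMaterials:
    def test_invalid_poisson_rejected(self):
        with pytest.raises(InvalidConfigError):
            MaterialProperties(stent_nu=0.7)

    def test_strut_inertia_matches_numeric_integration(self):
        xs = StrutCrossSection()
        assert xs.inertia == pytest.approx(0.115 * 0.145**3 / 12)
        # midpoint-rule integral of y^2 over the rectangle
        y = np.linspace(-xs.height / 2, xs.height / 2, 20001)
        dy = y[1] - y[0]
        yc = 0.5 * (y[:-1] + y[1:])
        num = float(np.sum(yc**2) * dy * xs.width)
        assert xs.inertia == pytest.approx(num, rel=1e-6)


class TestRigidity:
    def test_single_strut_contribution(self):
        mat, xs = MaterialProperties(), StrutCrossSection()
        spec = StentGraftSpec("Patient 1", "RRA", "nominal", 23, 6)
        r = spec.diameter_mm / 2
        got = effective_bending_rigidity(mat, xs, spec, 2, 1.0)
        expected = 1.0 + mat.stent_E * 2 * (xs.inertia + xs.area * r**2 / 2) + (
            mat.graft_E1 * np.pi * r**3 * mat.graft_thickness
        )
        assert got == pytest.approx(expected)

    def test_graft_tube_matches_annulus_integral(self):
        mat = MaterialProperties()
        spec = StentGraftSpec("Patient 1", "RRA", "nominal", 23, 6)
        r, t = 3.0, mat.graft_thickness
        thin_wall = mat.graft_E1 * np.pi * r**3 * t
        annulus_I = np.pi / 4 * ((r + t / 2) ** 4 - (r - t / 2) ** 4)
        assert thin_wall == pytest.approx(mat.graft_E1 * annulus_I, rel=0.01)

    def test_degenerate_composite_returns_artery_rigidity(self):
        mat = MaterialProperties(graft_thickness=0.0)
        xs = StrutCrossSection()
        spec = StentGraftSpec("Patient 1", "RRA", "nominal", 23, 6)
        assert effective_bending_rigidity(mat, xs, spec, 0, 123.0) == pytest.approx(123.0)

    def test_monotone_in_strut_count_section_and_thickness(self):
        spec = StentGraftSpec("Patient 1", "RRA", "nominal", 23, 6)
        xs = StrutCrossSection()
        base = effective_bending_rigidity(MaterialProperties(), xs, spec, 6, 100.0)
        more_struts = effective_bending_rigidity(MaterialProperties(), xs, spec, 8, 100.0)
        fatter = effective_bending_rigidity(
            MaterialProperties(), StrutCrossSection(0.2, 0.2), spec, 6, 100.0
        )
        thicker = effective_bending_rigidity(
            MaterialProperties(graft_thickness=0.4), xs, spec, 6, 100.0
        )
        assert more_struts > base and fatter > base and thicker > base > 100.0

    def test_composite_stiffer_than_artery(self):
        for spec in sg_catalog():
            assert effective_bending_rigidity(
                MaterialProperties(), StrutCrossSection(), spec, 6, 100.0
            ) > 100.0


class TestThreePointBending:
    def test_closed_form(self):
        assert three_point_bending_force(100.0, 30.0, 3.0) == pytest.approx(
            48 * 100 * 3 / 30**3
        )

    def test_zero_deflection_zero_force(self):
        assert three_point_bending_force(100.0, 30.0, 0.0) == 0.0

    def test_linearity_in_rigidity(self):
        f1 = three_point_bending_force(100.0, 30.0, 2.0)
        f2 = three_point_bending_force(200.0, 30.0, 2.0)
        assert f2 == pytest.approx(2 * f1)

    def test_plastic_regime_rejected(self):
        with pytest.raises(OutOfValidityError):
            three_point_bending_force(100.0, 30.0, 3.5)

    def test_against_numeric_beam_solve(self):
        # simply supported beam, midspan point load, 100-element FD solve
        EI, L, delta = 100.0, 30.0, 2.0
        n = 101
        x = np.linspace(0, L, n)
        h = x[1] - x[0]
        F = 1.0  # unit load; linear problem
        # bending moment of simply supported midspan load: M = F/2 * min(x, L-x)
        M = F / 2 * np.minimum(x, L - x)
        # integrate w'' = -M/EI with w(0)=w(L)=0 via second-difference solve
        A = np.zeros((n - 2, n - 2))
        idx = np.arange(n - 2)
        A[idx, idx] = -2.0
        A[idx[:-1], idx[:-1] + 1] = 1.0
        A[idx[1:], idx[1:] - 1] = 1.0
        w_inner = np.linalg.solve(A / h**2, -M[1:-1] / EI)
        delta_unit = -w_inner.min() if w_inner.min() < 0 else w_inner.max()
        stiffness_numeric = F / delta_unit
        stiffness_formula = three_point_bending_force(EI, L, delta) / delta
        assert stiffness_formula == pytest.approx(stiffness_numeric, rel=0.005)


class TestDeployment:
    def test_contract_arithmetic(self):
        spec = catalog_lookup("Patient 1", "RRA", "nominal")  # 23 x 7
        sg = deploy_geometric(straight_branch(40.0), spec, 4.0, 8.0)
        assert sg.protrusion_length == pytest.approx(4.0)
        assert sg.in_artery_length == pytest.approx(19.0)
        assert sg.flared_diameter_mm == 8.0

    def test_protrusion_within_clinical_band(self):
        spec = catalog_lookup("Patient 1", "RRA", "nominal")
        sg = deploy_geometric(straight_branch(40.0), spec, 3.9, 8.0)
        assert 3.4 <= sg.protrusion_length <= 4.3

    def test_too_long_for_branch_rejected(self):
        spec = catalog_lookup("Patient 2", "LRA", "longer")  # 28 x 5
        with pytest.raises(DeploymentInfeasibleError):
            deploy_geometric(straight_branch(20.0), spec, 4.0, 6.0)

    @pytest.mark.parametrize("protrusion", [0.0, 2.0, 4.3])
    def test_length_conservation(self, protrusion):
        spec = catalog_lookup("Patient 2", "RRA", "shorter")
        sg = deploy_geometric(straight_branch(40.0), spec, protrusion, 7.0)
        assert sg.in_artery_length + sg.protrusion_length == pytest.approx(spec.length_mm)
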