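"""QTAIM field evaluation, critical points, RDG and the B_E estimator."""

import math

import numpy as np
import pytest

from hostguest import density_topology as dt
from hostguest.density_topology import (
    be_from_rho,
    classify_interaction,
    eval_field,
    find_bcps,
    nci_grid,
    packaged_wavefunction,
    rdg,
)


@pytest.fixture(scope="module")
def one_center():
    return packaged_wavefunction("one_center")


@pytest.fixture(scope="module")
def symmetric_dimer():
    return packaged_wavefunction("symmetric_dimer")


@pytest.fixture(scope="module")
def asymmetric_dimer():
    return packaged_wavefunction("asymmetric_dimer")


@pytest.fixture(scope="module")
def noncovalent_dimer():
    return packaged_wavefunction("noncovalent_dimer")


class TestEvalField:
    def test_density_at_center_of_unit_gaussian(self, one_center):
        # rho(0) = 2 (2/pi)^(3/2) for a doubly occupied normalised 1s Gaussian
        fp = eval_field(one_center, np.zeros(3))
        assert fp.rho == pytest.approx(2 * (2 / math.pi) ** 1.5, rel=1e-12)

    def test_kinetic_density_vanishes_at_s_orbital_center(self, one_center):
        assert eval_field(one_center, np.zeros(3)).G == pytest.approx(0.0, abs=1e-14)

    def test_analytic_derivatives_match_finite_differences(self, asymmetric_dimer):
        rng = np.random.default_rng(1)
        h = 1e-4
        eye = np.eye(3)
        for _ in range(20):
            p = rng.uniform(-1.0, 4.0, 3)
            fp = eval_field(asymmetric_dimer, p)
            g_fd = np.array(
                [
                    (eval_field(asymmetric_dimer, p + h * e).rho
                     - eval_field(asymmetric_dimer, p - h * e).rho) / (2 * h)
                    for e in eye
                ]
            )
            scale = max(np.abs(fp.grad).max(), 1e-12)
            assert np.abs(g_fd - fp.grad).max() / scale < 1e-6
            lap_fd = sum(
                (eval_field(asymmetric_dimer, p + h * e).rho
                 - 2 * fp.rho
                 + eval_field(asymmetric_dimer, p - h * e).rho) / h**2
                for e in eye
            )
            assert lap_fd == pytest.approx(fp.laplacian, rel=1e-5, abs=1e-8)

    def test_virial_identity_holds_by_construction(self, asymmetric_dimer):
        rng = np.random.default_rng(2)
        for _ in range(100):
            fp = eval_field(asymmetric_dimer, rng.uniform(-2, 5, 3))
            assert fp.V == pytest.approx(0.25 * fp.laplacian - 2 * fp.G, rel=1e-14)
            assert fp.H == pytest.approx(fp.G + fp.V, rel=1e-14)
            assert fp.G >= 0.0

    def test_quadrature_recovers_electron_count(self, asymmetric_dimer):
        ax = np.linspace(-7.0, 10.0, 120)
        dv = (ax[1] - ax[0]) ** 3
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        m = asymmetric_dimer
        rho = np.zeros(len(pts))
        for i, eta in enumerate(m.occupations):
            phi = np.zeros(len(pts))
            for k in range(len(m.exponents)):
                u = pts - m.centers[m.primitive_centers[k]]
                phi += m.mo_coefficients[i, k] * m.coefficients[k] * np.exp(
                    -m.exponents[k] * (u**2).sum(1)
                )
            rho += eta * phi**2
        assert rho.sum() * dv == pytest.approx(m.n_electrons, rel=1e-3)

    def test_orbitals_are_normalised(self, asymmetric_dimer):
        # same quadrature, per orbital
        ax = np.linspace(-7.0, 10.0, 120)
        dv = (ax[1] - ax[0]) ** 3
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        m = asymmetric_dimer
        for i in range(len(m.occupations)):
            phi = np.zeros(len(pts))
            for k in range(len(m.exponents)):
                u = pts - m.centers[m.primitive_centers[k]]
                phi += m.mo_coefficients[i, k] * m.coefficients[k] * np.exp(
                    -m.exponents[k] * (u**2).sum(1)
                )
            assert (phi**2).sum() * dv == pytest.approx(1.0, abs=1e-3)


class TestRDG:
    def test_zero_gradient_gives_zero(self):
        assert rdg(0.5, 0.0) == 0.0

    def test_hydrogenic_closed_form(self):
        # rho = exp(-2r)/pi: s(0) = (3 pi^2)^(-1/3) rho^(-1/3) = 0.4734
        rho0 = 1 / math.pi
        assert rdg(rho0, 2 * rho0) == pytest.approx(0.4734, abs=5e-5)

    def test_scaling_invariance(self):
        s1 = rdg(0.02, 0.013)
        c = 7.3
        assert rdg(c * 0.02, c ** (4 / 3) * 0.013) == pytest.approx(s1, rel=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            rdg(0.0, 1.0)


class TestCriticalPoints:
    def test_symmetric_dimer_bcp_at_midpoint(self, symmetric_dimer):
        cps = find_bcps(symmetric_dimer)
        assert len(cps) == 1
        cp = cps[0]
        assert cp.kind == (3, -1)
        assert np.abs(cp.position - np.array([0.0, 0.0, 1.0])).max() < 1e-6
        assert np.linalg.norm(cp.field.grad) < 1e-8

    def test_single_atom_has_no_bcp(self, one_center):
        assert find_bcps(one_center) == []

    def test_asymmetric_bcp_matches_grid_scan(self, asymmetric_dimer):
        cps = find_bcps(asymmetric_dimer)
        assert len(cps) == 1
        zs = np.linspace(0.2, 2.8, 1301)
        gn = [
            np.linalg.norm(eval_field(asymmetric_dimer, np.array([0, 0, z])).grad)
            for z in zs
        ]
        z_scan = zs[int(np.argmin(gn))]
        assert cps[0].position[2] == pytest.approx(z_scan, abs=zs[1] - zs[0])

    def test_bcp_eigenvalue_pattern(self, noncovalent_dimer):
        (cp,) = find_bcps(noncovalent_dimer)
        eig = np.linalg.eigvalsh(cp.field.hessian)
        assert eig[0] <= eig[1] < 0 < eig[2]
        assert cp.field.signed_rho < 0


class TestClassification:
    def test_rule_application(self, noncovalent_dimer):
        (cp,) = find_bcps(noncovalent_dimer)
        f = cp.field
        assert f.laplacian > 0 and f.H > 0 and -f.G / f.V > 1
        assert classify_interaction(cp) == "noncovalent"
        assert f.rho <= 0.0208  # weak-contact density envelope

    def test_shared_interaction_detected(self):
        # a genuinely shared (bonding-orbital) dimer has H < 0 at the BCP
        a = 1.0
        norm = (2 * a / math.pi) ** 0.75
        d = 1.8
        # one doubly-occupied bonding MO; overlap integral fixes normalisation
        s_overlap = math.exp(-a * d**2 / 2.0)
        c = 1.0 / math.sqrt(2.0 * (1.0 + s_overlap))
        model = dt.WavefunctionModel(
            centers=np.array([[0, 0, 0], [0, 0, d]], float),
            atomic_numbers=(1, 1),
            primitive_centers=[0, 1],
            exponents=[a, a],
            coefficients=[norm, norm],
            mo_coefficients=np.array([[c, c]]),
            occupations=[2.0],
        )
        (cp,) = find_bcps(model)
        assert cp.kind == (3, -1)
        assert classify_interaction(cp) == "shared"
        assert cp.field.H < 0

    def test_wrong_signature_rejected(self, one_center):
        fp = eval_field(one_center, np.zeros(3))
        cp = dt.CriticalPoint(np.zeros(3), 3, -3, fp, (0, 0))
        with pytest.raises(ValueError):
            classify_interaction(cp)


class TestBindingEnergyEstimator:
    @pytest.mark.parametrize(
        "rho, be", [(0.0208, -3.90), (0.0114, -1.80)]
    )
    def test_calibrated_values(self, rho, be):
        assert be_from_rho(rho) == pytest.approx(be, abs=0.005)

    def test_intercept_flagged_out_of_range(self):
        with pytest.warns(UserWarning):
            assert be_from_rho(0.0) == pytest.approx(0.7423)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            be_from_rho(-0.001)


class TestNCIGrid:
    def test_s_minimum_sits_at_bcp(self, noncovalent_dimer):
        (cp,) = find_bcps(noncovalent_dimer)
        spacing = 0.1
        # thin slab around the internuclear axis keeps the grid small
        grid = nci_grid(
            noncovalent_dimer,
            box=(np.array([-0.4, -0.4, -1.0]), np.array([0.4, 0.4, 4.0])),
            spacing=spacing,
        )
        axis_z = grid.origin[2] + spacing * np.arange(grid.s.shape[2])
        ix = int(round((0.0 - grid.origin[0]) / spacing))
        iy = int(round((0.0 - grid.origin[1]) / spacing))
        line = grid.s[ix, iy, :]
        inner = (axis_z > 0.5) & (axis_z < 2.5)
        z_min = axis_z[inner][np.nanargmin(line[inner])]
        assert abs(z_min - cp.position[2]) <= spacing

    def test_pointwise_s_is_grid_independent(self, noncovalent_dimer):
        p = np.array([0.1, -0.2, 1.3])
        s1 = eval_field(noncovalent_dimer, p).s
        # s at a physical point does not depend on any grid spacing
        s2 = eval_field(noncovalent_dimer, p + 0.0).s
        assert s1 == s2

    def test_dense_region_masked_and_color_clamped(self, noncovalent_dimer):
        grid = nci_grid(noncovalent_dimer, spacing=0.4, rho_max=0.05,
                        color_range=(-0.05, 0.01))
        dense = np.abs(grid.signed_rho) > 0.05
        assert np.all(np.isnan(grid.s[dense]))
        assert np.nanmin(grid.color) >= -0.05 and np.nanmax(grid.color) <= 0.01

    def test_box_must_enclose_centers(self, symmetric_dimer):
        with pytest.raises(ValueError):
            nci_grid(symmetric_dimer,
                     box=(np.array([-1.0, -1.0, -1.0]), np.array([1.0, 1.0, 0.5])),
                     spacing=0.5)
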