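"""Finite-element solver: meshing, patch tests, locking control, contact."""

import numpy as np
import pytest

from tfm3d import fe
from tfm3d import materials as M
from tfm3d import mesh as msh
from tfm3d.foundation import oedometric_modulus


def confined_compression_bc(mesh, delta):
    """Bottom fixed, lateral faces normal-fixed, top pushed down by delta."""
    bc = fe.fix_bottom(mesh)
    bc.fix(mesh.node_sets["x_faces"], components=(0,))
    bc.fix(mesh.node_sets["y_faces"], components=(1,))
    top = mesh.node_sets["top"]
    bc.prescribe(top, np.tile([0.0, 0.0, -delta], (len(top), 1)), components=(2,))
    return bc


class TestMeshing:
    def test_grid_counts_match_dic_lattice(self):
        m = msh.build_grid_mesh(3, 3, 0.3, 0.15, nz=3)
        assert m.n_elems == 20 * 20 * 3 == 1200
        assert len(m.node_sets["top"]) == 21 * 21
        assert m.spacing == pytest.approx(0.15)

    def test_element_density_near_reference(self):
        # 0.15 mm lattice with 3 layers over 0.3 mm: ~444 elements/mm^3,
        # consistent with the reference model's ~475
        density = 1.0 / (0.15**2 * 0.1)
        assert 400 < density < 500

    def test_jacobians_positive(self):
        assert msh.element_jacobians_positive(msh.build_grid_mesh(0.6, 0.45, 0.3, 0.15))
        assert msh.element_jacobians_positive(
            msh.build_graded_mesh(0.6, 2.0, 0.15, 0.3))

    def test_non_commensurate_rejected(self):
        with pytest.raises(msh.MeshingError):
            msh.build_grid_mesh(3.07, 3.0, 0.3, 0.15)

    def test_graded_core_keeps_lattice(self):
        m = msh.build_graded_mesh(0.9, 3.0, 0.15, 0.3)
        core = m.xs[np.abs(m.xs) <= 0.9 + 1e-9]
        np.testing.assert_allclose(np.diff(core), 0.15, rtol=1e-9)
        assert m.xs[0] == -3.0 and m.xs[-1] == 3.0

    def test_vtk_export(self, tmp_path):
        m = msh.build_grid_mesh(0.3, 0.3, 0.3, 0.15, nz=1)
        p = tmp_path / "mesh.vtk"
        msh.write_vtk(p, m, point_data={"u": np.zeros((m.n_nodes, 3))})
        text = p.read_text()
        assert "UNSTRUCTURED_GRID" in text and f"POINTS {m.n_nodes}" in text


class TestLinearSolves:
    def test_patch_test_linear_field_exact(self):
        # arbitrary affine displacement prescribed on the whole boundary must
        # be reproduced exactly by trilinear elements
        m = msh.build_grid_mesh(0.45, 0.45, 0.3, 0.15, nz=2)
        mat = M.LinearElasticMaterial(E=1.7, nu=0.45)
        A = np.array([[1e-3, 2e-4, 0.0], [3e-4, -5e-4, 1e-4], [0.0, 2e-4, 4e-4]])
        bnd = np.unique(np.concatenate([m.node_sets[s]
                                        for s in ("top", "bottom", "lateral")]))
        bc = fe.DirichletBC(m.n_nodes).prescribe(bnd, m.nodes[bnd] @ A.T)
        res = fe.solve_dirichlet(m, mat, bc)
        assert np.abs(res.u - m.nodes @ A.T).max() < 1e-12

    def test_zero_bc_gives_zero_state(self):
        m = msh.build_grid_mesh(0.45, 0.45, 0.3, 0.15, nz=2)
        bc = fe.fix_bottom(m)
        bc.prescribe(m.node_sets["top"], np.zeros((len(m.node_sets["top"]), 3)))
        res = fe.solve_dirichlet(m, M.LinearElasticMaterial(E=1.7, nu=0.45), bc)
        assert np.abs(res.u).max() == 0.0
        assert np.abs(res.reactions).max() < 1e-14

    def test_confined_layer_stiffness_matches_oedometric(self):
        for nu in (0.3, 0.45):
            k = fe.confined_layer_stiffness(1.7, nu, 0.3)
            assert k == pytest.approx(oedometric_modulus(1.7, nu) / 0.3, rel=1e-6)


@pytest.fixture(scope="module")
def oedo_result(avg_pdms):
    m = msh.build_grid_mesh(0.6, 0.6, 0.3, 0.15, nz=3)
    bc = confined_compression_bc(m, delta=0.05 * 0.3)
    return m, fe.solve_dirichlet(m, avg_pdms, bc)


class TestOgdenSolves:

    def test_locking_free_confined_compression(self, avg_pdms, oedo_result):
        # at nu = 0.45 a locking formulation badly overestimates this
        m, res = oedo_result
        Fz = res.reactions[m.node_sets["top"], 2].sum()
        M_eff = -Fz / (0.6 * 0.6) / 0.05
        M_ref = oedometric_modulus(avg_pdms.youngs_modulus, avg_pdms.poisson)
        assert M_eff == pytest.approx(M_ref, rel=0.02)

    def test_global_equilibrium(self, oedo_result):
        _, res = oedo_result
        total = np.abs(res.reactions.sum(axis=0)).max()
        assert total <= 1e-6 * np.abs(res.reactions).sum()

    def test_top_bottom_balance(self, oedo_result):
        m, res = oedo_result
        top = res.reactions[m.node_sets["top"]].sum(axis=0)
        bot = res.reactions[m.node_sets["bottom"]].sum(axis=0)
        # lateral faces carry only normal constraints; vertical components balance
        assert top[2] == pytest.approx(-bot[2], rel=1e-8)

    def test_newton_quadratic_convergence(self, oedo_result):
        _, res = oedo_result
        r = np.asarray(res.log[-1].residuals)
        e = r / r[0]
        assert len(e) >= 3
        assert e[2] < e[1] ** 1.5  # superlinear (quadratic up to roundoff)

    def test_peak_strain_tracks_compression(self, oedo_result):
        _, res = oedo_result
        # delta/h = 0.05 confined: principal nominal strain ~ 5%
        assert res.peak_principal_strain == pytest.approx(0.05, rel=0.05)

    def test_simple_shear_traction(self, avg_pdms):
        # full affine simple-shear field: mean top traction = G * gamma
        m = msh.build_grid_mesh(0.6, 0.6, 0.3, 0.15, nz=3)
        gamma = 1e-3
        A = np.zeros((3, 3))
        A[0, 2] = gamma
        bnd = np.unique(np.concatenate([m.node_sets[s]
                                        for s in ("top", "bottom", "lateral")]))
        bc = fe.DirichletBC(m.n_nodes).prescribe(bnd, m.nodes[bnd] @ A.T)
        res = fe.solve_dirichlet(m, avg_pdms, bc)
        Fx = res.reactions[m.node_sets["top"], 0].sum()
        assert Fx / 0.36 == pytest.approx(avg_pdms.shear_modulus * gamma, rel=0.01)

    def test_rigid_translation_strain_free(self, avg_pdms):
        m = msh.build_grid_mesh(0.45, 0.45, 0.3, 0.15, nz=2)
        all_nodes = np.arange(m.n_nodes)
        bc = fe.DirichletBC(m.n_nodes).prescribe(
            all_nodes, np.tile([0.01, -0.02, 0.005], (m.n_nodes, 1)))
        res = fe.solve_dirichlet(m, avg_pdms, bc)
        assert res.peak_principal_strain == pytest.approx(0.0, abs=1e-10)

    def test_uniaxial_stretch_strain(self, avg_pdms):
        m = msh.build_grid_mesh(0.45, 0.45, 0.3, 0.15, nz=2)
        A = np.diag([0.12, 0.0, 0.0])
        all_nodes = np.arange(m.n_nodes)
        bc = fe.DirichletBC(m.n_nodes).prescribe(all_nodes, m.nodes @ A.T)
        res = fe.solve_dirichlet(m, avg_pdms, bc)
        field, peak = fe.max_principal_strain(res)
        assert peak == pytest.approx(0.12, rel=1e-9)
        np.testing.assert_allclose(field, 0.12, rtol=1e-9)

    def test_reactions_only_on_constrained_nodes(self, oedo_result):
        m, res = oedo_result
        free = ~res.fixed_mask.any(axis=1)
        assert np.abs(res.reactions[free]).max() == 0.0

    def test_extract_top_reactions_contract(self, avg_pdms):
        m = msh.build_grid_mesh(0.45, 0.45, 0.3, 0.15, nz=2)
        f = np.zeros((m.n_nodes, 3))
        f[m.node_sets["top"], 2] = -1e-5
        res = fe.solve_neumann(m, avg_pdms, f)  # top unconstrained
        with pytest.raises(ValueError):
            fe.extract_top_reactions(res, m)


class TestContact:
    def test_patch_exceeding_mesh_rejected(self, avg_pdms):
        m = msh.build_grid_mesh(0.6, 0.6, 0.3, 0.15, nz=2)
        with pytest.raises(fe.ContactError):
            fe.solve_sphere_indentation(m, avg_pdms, fe.RigidSphere(radius=8.5),
                                        target_force=1.0)

    def test_bad_sphere_rejected(self):
        with pytest.raises(ValueError):
            fe.RigidSphere(radius=-1.0)
        with pytest.raises(NotImplementedError):
            fe.RigidSphere(radius=1.0, friction="coulomb")

    def test_force_match_and_symmetry(self, sphere_small):
        _, grid, truth = sphere_small
        # converged total force within 0.5% of the target
        assert truth.magnitude == pytest.approx(0.05, rel=0.005)
        w = truth.displacements[..., 2]
        # axisymmetric load on a symmetric lattice: mirror-symmetric field
        np.testing.assert_allclose(w, w[::-1, :], atol=1e-9)
        np.testing.assert_allclose(w, w[:, ::-1], atol=1e-9)

    def test_contact_forces_compressive(self, sphere_small):
        _, _, truth = sphere_small
        fz = truth.tractions[..., 2]
        assert fz.min() < 0 and fz.max() <= 1e-12
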