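"""Verification of the constant-strain-tetrahedron elastic solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splintfea import fea
from splintfea.meshing import DentitionModel, boundary_faces, box_mesh

from .oracles import dense_element_stiffness, dense_solve

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)

# exact stiffness of the unit right tet for E=1, nu=0, derived symbolically
# (integer matrix / 12); frozen before the solver was written
K_UNIT_TET_12 = np.array(
    [
        [4, 1, 1, -2, -1, -1, -1, 0, 0, -1, 0, 0],
        [1, 4, 1, 0, -1, 0, -1, -2, -1, 0, -1, 0],
        [1, 1, 4, 0, 0, -1, 0, 0, -1, -1, -1, -2],
        [-2, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0],
        [-1, -1, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0],
        [-1, 0, -1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
        [-1, -1, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0],
        [0, -2, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0],
        [0, -1, -1, 0, 0, 0, 0, 0, 1, 0, 1, 0],
        [-1, 0, -1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
        [0, -1, -1, 0, 0, 0, 0, 0, 1, 0, 1, 0],
        [0, 0, -2, 0, 0, 0, 0, 0, 0, 0, 0, 2],
    ],
    dtype=float,
)


class TestElementStiffness:
    def test_matches_symbolic_oracle(self):
        mat = fea.MaterialModel(1.0, 1e-12)
        K = fea.element_stiffness(UNIT_TET, mat)
        assert np.allclose(K, K_UNIT_TET_12 / 12.0, atol=1e-9)

    def test_symmetric(self, rng):
        coords = UNIT_TET + rng.normal(0, 0.1, (4, 3))
        K = fea.element_stiffness(coords, fea.TOOTH)
        assert np.allclose(K, K.T, rtol=1e-10)

    def test_six_rigid_body_modes(self):
        K = fea.element_stiffness(UNIT_TET, fea.PMMA)
        eig = np.linalg.eigvalsh(K)
        assert (np.abs(eig) < 1e-9 * np.abs(eig).max()).sum() == 6

    def test_rigid_translation_annihilated(self):
        K = fea.element_stiffness(UNIT_TET, fea.PDL)
        for axis in range(3):
            u = np.zeros(12)
            u[axis::3] = 1.0
            assert np.allclose(K @ u, 0.0, atol=1e-12)

    def test_degenerate_tet_rejected(self):
        flat = UNIT_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]  # coplanar
        with pytest.raises(ValueError, match="degenerate"):
            fea.element_stiffness(flat, fea.TOOTH)
        inverted = UNIT_TET[[0, 2, 1, 3]]
        with pytest.raises(ValueError):
            fea.element_stiffness(inverted, fea.TOOTH)

    @given(st.floats(min_value=0.05, max_value=0.45))
    def test_agrees_with_jacobian_route(self, nu):
        K = fea.element_stiffness(UNIT_TET, fea.MaterialModel(1234.5, nu))
        Kd = dense_element_stiffness(UNIT_TET, 1234.5, nu)
        assert np.allclose(K, Kd, rtol=1e-10)


class TestVonMises:
    def test_uniaxial(self):
        assert fea.recover_von_mises([5.0, 0, 0, 0, 0, 0]) == pytest.approx(5.0)

    def test_hydrostatic_is_zero(self):
        assert fea.recover_von_mises([7.0, 7.0, 7.0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        assert fea.recover_von_mises([0, 0, 0, 1.0, 0, 0]) == pytest.approx(np.sqrt(3.0))

    def test_tensor_and_voigt_agree(self, rng):
        s = rng.normal(size=(3, 3))
        s = 0.5 * (s + s.T)
        voigt = [s[0, 0], s[1, 1], s[2, 2], s[0, 1], s[1, 2], s[2, 0]]
        assert fea.recover_von_mises(s) == pytest.approx(fea.recover_von_mises(voigt))

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           st.floats(-100, 100))
    def test_nonnegative_and_pressure_invariant(self, sv, p):
        vm = fea.recover_von_mises(sv)
        assert vm >= 0.0
        shifted = [sv[0] + p, sv[1] + p, sv[2] + p, sv[3], sv[4], sv[5]]
        assert fea.recover_von_mises(shifted) == pytest.approx(vm, abs=1e-6 * (1 + abs(p)))


def _fix_and_load(model, fixed_mask, forces=None):
    lc = fea.LoadCase(nodal_forces=np.zeros((model.n_nodes, 3)),
                      fixed_nodes=np.flatnonzero(fixed_mask))
    if forces is not None:
        lc.nodal_forces[:] = forces
    return lc


class TestAssembly:
    def test_single_element_assembly_equals_element_matrix(self):
        model = DentitionModel(
            nodes=UNIT_TET.copy(),
            elements=np.array([[0, 1, 2, 3]]),
            element_region=np.array([0]),
            region_names=("solo",),
        )
        K = fea.assemble(model, {"solo": fea.PMMA}).toarray()
        assert np.allclose(K, fea.element_stiffness(UNIT_TET, fea.PMMA), atol=1e-10)

    def test_matvec_matches_dense_oracle_on_24_element_mesh(self, rng):
        m = box_mesh((2, 2, 1), 1.0)
        assert m.n_elements == 24
        K = fea.assemble(m, {"box": fea.TOOTH})
        from .oracles import dense_assemble

        Kd = dense_assemble(m.nodes, m.elements,
                            [(fea.TOOTH.young_modulus_MPa, fea.TOOTH.poisson_ratio)] * m.n_elements)
        v = rng.normal(size=K.shape[0])
        assert np.allclose(K @ v, Kd @ v, rtol=1e-10, atol=1e-10 * np.abs(Kd @ v).max())

    def test_missing_material_rejected(self, toy_model):
        with pytest.raises(KeyError, match="no material"):
            fea.assemble(toy_model, {"31": fea.TOOTH})

    def test_six_zero_energy_modes_before_constraints(self):
        m = box_mesh((1, 1, 2), 1.0)
        K = fea.assemble(m, {"box": fea.PMMA}).toarray()
        eig = np.linalg.eigvalsh(K)
        assert (np.abs(eig) < 1e-9 * eig.max()).sum() == 6


class TestOcclusalLoad:
    def test_even_split_and_conservation(self, toy_model):
        lc = fea.apply_occlusal_load(toy_model, "occlusal_31", 44.3)
        nodes = toy_model.node_set("occlusal_31")
        per_node = lc.nodal_forces[nodes]
        assert np.allclose(per_node[:, 2], -44.3 / len(nodes))
        assert lc.nodal_forces.sum(axis=0) == pytest.approx([0, 0, -44.3], abs=1e-12)

    def test_disjoint_sets_accumulate(self, toy_model):
        lc = fea.apply_occlusal_load(toy_model, "occlusal_31", 10.0)
        lc = fea.apply_occlusal_load(toy_model, "occlusal_41", 20.0, load_case=lc)
        assert lc.nodal_forces[:, 2].sum() == pytest.approx(-30.0)

    def test_empty_or_unknown_set_rejected(self, toy_model):
        with pytest.raises(KeyError):
            fea.apply_occlusal_load(toy_model, "occlusal_99", 1.0)
        with pytest.raises(ValueError, match="unit"):
            fea.apply_occlusal_load(toy_model, "occlusal_31", 1.0, direction=(0, 0, -2))


class TestSolve:
    def test_axial_bar_matches_closed_form(self):
        """delta = FL/EA for a PMMA bar: 10 mm, 1 mm^2, E = 2200 MPa, 22 N."""
        m = box_mesh((10, 1, 1), 1.0)
        mats = {"box": fea.MaterialModel(2200.0, 1e-9)}
        x = m.nodes[:, 0]
        bf = boundary_faces(m)
        tip_faces = bf.faces[bf.normals[:, 0] > 0.99]
        lc = fea.uniform_traction_load(m, tip_faces, (22.0, 0.0, 0.0))
        lc.fixed_nodes = np.flatnonzero(np.isclose(x, 0.0))
        sol = fea.solve_system(m, mats, lc)
        tip = np.flatnonzero(np.isclose(x, 10.0))
        assert np.allclose(sol.displacements[tip, 0], 0.1, rtol=1e-6)

    def test_patch_test_linear_field_exact(self, rng):
        """A linear displacement field imposed on the boundary of an irregular
        patch is reproduced exactly in the interior, with constant stress."""
        m = box_mesh((2, 2, 2), 1.0)
        interior = np.flatnonzero(
            np.all((m.nodes > 0.01) & (m.nodes < 1.99), axis=1)
        )
        assert len(interior) == 1
        nodes = m.nodes.copy()
        nodes[interior[0]] += [0.21, -0.13, 0.17]  # break the structured symmetry
        m.nodes = nodes
        A = np.array([[1e-3, 2e-4, -1e-4], [0, -5e-4, 3e-4], [2e-4, 0, 8e-4]])
        exact = m.nodes @ A.T
        boundary = np.setdiff1d(np.arange(m.n_nodes), interior)
        lc = fea.LoadCase(
            nodal_forces=np.zeros((m.n_nodes, 3)),
            prescribed={int(i): exact[i] for i in boundary},
        )
        sol = fea.solve_system(m, {"box": fea.TOOTH}, lc)
        err = np.abs(sol.displacements - exact).max() / np.abs(exact).max()
        assert err < 1e-8
        assert np.allclose(sol.element_stress, sol.element_stress[0], rtol=1e-7)

    def test_doubling_load_doubles_displacement(self, toy_model):
        mats = fea.default_materials(toy_model)
        lc1 = fea.apply_occlusal_load(toy_model, "occlusal_31", 10.0)
        lc1.fixed_nodes = toy_model.node_set("pdl_outer")
        lc2 = fea.apply_occlusal_load(toy_model, "occlusal_31", 20.0)
        lc2.fixed_nodes = toy_model.node_set("pdl_outer")
        K = fea.assemble(toy_model, mats)
        u1 = fea.solve_system(toy_model, mats, lc1, stiffness=K).displacements
        u2 = fea.solve_system(toy_model, mats, lc2, stiffness=K).displacements
        assert np.allclose(u2, 2 * u1, rtol=1e-9, atol=1e-15)

    def test_halving_modulus_doubles_displacement(self):
        m = box_mesh((4, 1, 1), 0.5)
        x = m.nodes[:, 0]
        lc = _fix_and_load(m, np.isclose(x, 0.0))
        lc.nodal_forces[np.isclose(x, 4.0), 2] = -1.0
        u_full = fea.solve_system(m, {"box": fea.MaterialModel(2000.0, 0.3)}, lc).displacements
        u_half = fea.solve_system(m, {"box": fea.MaterialModel(1000.0, 0.3)}, lc).displacements
        assert np.allclose(u_half, 2 * u_full, rtol=1e-9)

    def test_displacements_match_dense_oracle(self, rng):
        m = box_mesh((2, 2, 1), 1.0)  # 24 elements
        E, nu = 5000.0, 0.3
        fixed = np.flatnonzero(np.isclose(m.nodes[:, 0], 0.0))
        forces = np.zeros((m.n_nodes, 3))
        free = np.setdiff1d(np.arange(m.n_nodes), fixed)
        forces[free] = rng.normal(0, 1.0, (len(free), 3))
        lc = fea.LoadCase(nodal_forces=forces, fixed_nodes=fixed)
        sol = fea.solve_system(m, {"box": fea.MaterialModel(E, nu)}, lc)
        u_ref = dense_solve(m.nodes, m.elements, [(E, nu)] * m.n_elements, fixed, forces)
        assert np.allclose(sol.displacements, u_ref, rtol=1e-9, atol=1e-12 * np.abs(u_ref).max())

    def test_global_equilibrium(self, toy_model):
        mats = fea.default_materials(toy_model)
        lc = fea.apply_occlusal_load(toy_model, "occlusal_32", 30.0)
        lc.fixed_nodes = toy_model.node_set("pdl_outer")
        sol = fea.solve_system(toy_model, mats, lc)
        total = sum(sol.reactions.values()) + lc.nodal_forces.sum(axis=0)
        applied = np.linalg.norm(lc.nodal_forces.sum(axis=0))
        assert np.linalg.norm(total) / applied < 1e-6

    def test_unconstrained_system_names_missing_constraint(self, toy_model):
        lc = fea.apply_occlusal_load(toy_model, "occlusal_31", 1.0)
        with pytest.raises(ValueError, match="fixed"):
            fea.solve_system(toy_model, fea.default_materials(toy_model), lc)

    def test_cantilever_converges_to_euler_bernoulli(self):
        """Tip deflection error vs FL^3/3EI strictly decreases under
        refinement (CST is stiff in bending but convergent)."""
        L, t, E, F = 8.0, 1.0, 2000.0, 1.0
        delta_eb = F * L**3 / (3 * E * (t**4 / 12))
        errors = []
        for h in (1.0, 0.5, 0.25):
            m = box_mesh((L, t, t), h)
            x = m.nodes[:, 0]
            lc = _fix_and_load(m, np.isclose(x, 0.0))
            tip = np.flatnonzero(np.isclose(x, L))
            lc.nodal_forces[tip, 2] = -F / len(tip)
            sol = fea.solve_system(m, {"box": fea.MaterialModel(E, 0.3)}, lc)
            tip_def = -sol.displacements[tip, 2].mean()
            errors.append(abs(tip_def - delta_eb) / delta_eb)
        assert errors[0] > errors[1] > errors[2]

    def test_tied_pairs_equal_merged_mesh(self):
        """Bonding two stacked blocks node-by-node reproduces the monolithic
        solution (the constraint-equation route for non-merged interfaces)."""
        merged = box_mesh((1, 1, 2), 0.5)
        bottom = box_mesh((1, 1, 1), 0.5)
        top = box_mesh((1, 1, 1), 0.5, origin=(0, 0, 1.0))
        n_b = bottom.n_nodes
        model = DentitionModel(
            nodes=np.vstack([bottom.nodes, top.nodes]),
            elements=np.vstack([bottom.elements, top.elements + n_b]),
            element_region=np.concatenate([bottom.element_region,
                                           top.element_region + 1]),
            region_names=("lower", "upper"),
        )
        iface_b = np.flatnonzero(np.isclose(bottom.nodes[:, 2], 1.0))
        ties = []
        for i in iface_b:
            j = np.flatnonzero(np.all(np.isclose(top.nodes, bottom.nodes[i]), axis=1))[0]
            ties.append((int(j) + n_b, int(i)))  # slave in upper, master in lower

        mat = fea.MaterialModel(2200.0, 0.35)

        def run(m, ties=()):
            z = m.nodes[:, 2]
            lc = fea.LoadCase(nodal_forces=np.zeros((m.n_nodes, 3)),
                              fixed_nodes=np.flatnonzero(np.isclose(z, 0.0)),
                              tied_pairs=ties)
            topn = np.flatnonzero(np.isclose(z, 2.0))
            lc.nodal_forces[topn, 0] = 1.0 / len(topn)
            mats = {r: mat for r in m.region_names}
            return fea.solve_system(m, mats, lc)

        u_ref = run(merged).displacements
        sol = run(model, ties)
        # compare at matching coordinates
        for i, p in enumerate(merged.nodes):
            j = np.flatnonzero(np.all(np.isclose(model.nodes, p), axis=1))[0]
            assert np.allclose(sol.displacements[j], u_ref[i], rtol=1e-8, atol=1e-14)
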