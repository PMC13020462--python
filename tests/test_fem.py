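"""Conduction FEM: element stiffness, terminal solves, conservation."""

import numpy as np
import pytest

from thoraxfem import (SolveSpec, assemble_system,
                       check_current_conservation, cylinder_mesh,
                       solve_injection, uniform_table)
from thoraxfem.mesh import TetMesh
from thoraxfem.tissues import default_table

I0 = 1e-3


def _single_tet_mesh():
    nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return TetMesh(nodes=nodes, tets=tets,
                   tet_labels=np.zeros(1, dtype=np.int32),
                   label_names={0: "medium"}, boundary_faces=faces,
                   face_labels=np.zeros(4, dtype=np.int32),
                   face_owners=np.zeros(4, dtype=np.int64),
                   patch_names={0: "outer"})


class TestAssembly:
    def test_reference_tet_stiffness_by_hand(self):
        # unit reference tet, kappa = 2: gradients of the barycentric
        # functions are (-1,-1,-1), e_x, e_y, e_z; volume 1/6, so
        # K = kappa/6 * G G^T, computed here independently
        mesh = _single_tet_mesh()
        system = assemble_system(mesh, uniform_table(2.0), SolveSpec())
        G = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        expected = 2.0 / 6.0 * G @ G.T
        assert np.allclose(system.K.toarray(), expected, atol=1e-14)

    def test_operator_annihilates_constants(self, unit_cube_system):
        _, system = unit_cube_system
        ones = np.ones(system.n_dofs)
        norm = abs(system.K).sum()
        assert np.abs(system.K @ ones).max() <= 1e-12 * norm

    def test_assembly_linear_in_conductivity(self):
        mesh = _single_tet_mesh()
        K1 = assemble_system(mesh, uniform_table(1.0), SolveSpec()).K
        K2 = assemble_system(mesh, uniform_table(2.0), SolveSpec()).K
        assert np.allclose((2 * K1 - K2).toarray(), 0.0, atol=1e-14)

    def test_missing_property_row_names_tissue_and_frequency(
            self, coarser_mesh):
        with pytest.raises(KeyError, match=r"2000"):
            assemble_system(coarser_mesh, default_table(),
                            SolveSpec(frequency=2000.0))


class TestTerminalSolves:
    def test_cube_reproduces_bar_conductance(self, unit_cube_system):
        # 0.1 m cube, full-face electrodes, sigma 0.5: R = L/(kappa*A) = 2
        _, system = unit_cube_system
        sol = solve_injection(system, "electrode_A", "electrode_B")
        Z = sol.electrode_potentials["electrode_A"] / I0
        assert Z == pytest.approx(0.1 / (0.5 * 0.1**2), rel=1e-9)

    def test_cylinder_linear_potential_and_resistance(self, small_cylinder):
        mesh, system = small_cylinder
        sol = solve_injection(system, "electrode_A", "electrode_B")
        coeff = np.polyfit(mesh.nodes[:, 2], sol.V, 1)
        assert np.abs(np.polyval(coeff, mesh.nodes[:, 2]) - sol.V).max() \
            < 1e-12
        Z = sol.electrode_potentials["electrode_A"] / I0
        R = 0.10 / (0.5 * np.pi * 0.03**2)
        assert Z == pytest.approx(R, rel=0.01)

    def test_swapping_terminals_negates_potential(self, small_cylinder):
        _, system = small_cylinder
        ab = solve_injection(system, "electrode_A", "electrode_B")
        ba = solve_injection(system, "electrode_B", "electrode_A")
        shift = ab.V + ba.V       # constant after re-grounding
        assert np.ptp(shift) < 1e-9

    def test_current_scales_field_linearly(self, small_cylinder):
        mesh, _ = small_cylinder
        tbl = uniform_table(0.5)
        s1 = assemble_system(mesh, tbl, SolveSpec(I0=1e-3))
        s2 = assemble_system(mesh, tbl, SolveSpec(I0=2e-3))
        v1 = solve_injection(s1, "electrode_A", "electrode_B").V
        v2 = solve_injection(s2, "electrode_A", "electrode_B").V
        assert np.allclose(v2, 2 * v1, atol=1e-12 * np.abs(v1).max())

    def test_sink_patch_grounded(self, coarser_result):
        assert abs(coarser_result.sol_AB.electrode_potentials[
            "electrode_B"]) == 0.0
        # reciprocal solve is shifted so its own sink reads zero
        assert abs(coarser_result.sol_CD.electrode_potentials[
            "electrode_D"]) == 0.0

    def test_iterative_matches_direct(self, small_cylinder):
        mesh, system = small_cylinder
        direct = solve_injection(system, "electrode_A", "electrode_B")
        it_sys = assemble_system(mesh, uniform_table(0.5),
                                 SolveSpec(solver="iterative",
                                           rel_tolerance=1e-12))
        it = solve_injection(it_sys, "electrode_A", "electrode_B")
        assert np.abs(it.V - direct.V).max() < 1e-6 * np.abs(direct.V).max()

    def test_unknown_patch_rejected(self, small_cylinder):
        _, system = small_cylinder
        with pytest.raises(KeyError):
            solve_injection(system, "electrode_X", "electrode_B")

    def test_node_permutation_invariance(self):
        mesh = cylinder_mesh(0.03, 0.08, 0.01)
        perm = np.random.default_rng(7).permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        shuffled = TetMesh(
            nodes=mesh.nodes[perm], tets=inv[mesh.tets],
            tet_labels=mesh.tet_labels, label_names=mesh.label_names,
            boundary_faces=inv[mesh.boundary_faces],
            face_labels=mesh.face_labels, face_owners=mesh.face_owners,
            patch_names=mesh.patch_names)
        tbl = uniform_table(0.5)
        v0 = solve_injection(assemble_system(mesh, tbl, SolveSpec()),
                             "electrode_A", "electrode_B").V
        v1 = solve_injection(assemble_system(shuffled, tbl, SolveSpec()),
                             "electrode_A", "electrode_B").V
        assert np.abs(v1 - v0[perm]).max() < 1e-9


class TestConservation:
    def test_converged_solve_passes(self, coarser_result):
        rep = check_current_conservation(coarser_result.sol_AB)
        assert rep["passed"]
        assert rep["consistent_patch_currents"]["electrode_A"] == \
            pytest.approx(I0, rel=0.005)
        assert rep["consistent_patch_currents"]["electrode_B"] == \
            pytest.approx(-I0, rel=0.005)
        assert abs(rep["total_consistent_current"]) <= 0.005 * I0
        # floating sense electrodes draw no net current
        for name in ("electrode_C", "electrode_D"):
            assert abs(rep["consistent_patch_currents"][name]) <= 0.005 * I0
        # the insulating-boundary condition holds in its consistent (weak)
        # form: the residual vanishes at every non-terminal dof, so the net
        # consistent flux through all non-electrode boundary is zero
        sol = coarser_result.sol_AB
        system = sol.system
        x = np.empty(system.n_dofs)
        x[system.dof_of_node] = sol.V
        r = system.K @ x
        non_terminal = np.ones(system.n_dofs, dtype=bool)
        for dof in system.electrode_dofs.values():
            non_terminal[dof] = False
        assert np.abs(r[non_terminal]).sum() <= 0.005 * I0
        # raw one-sided flux on the faceted curved surface carries chordal
        # noise; bound it loosely
        assert abs(rep["surface_patch_currents"]["outer"]) <= 0.05 * I0
        assert abs(rep["surface_patch_currents"]["airway_wall"]) <= \
            0.05 * I0

    def test_corrupted_solution_flagged(self, small_cylinder):
        from dataclasses import replace

        _, system = small_cylinder
        sol = solve_injection(system, "electrode_A", "electrode_B")
        bad = replace(sol, V=1.05 * sol.V,
                      patch_currents={k: 1.05 * v
                                      for k, v in sol.patch_currents.items()})
        rep = check_current_conservation(bad)
        assert not rep["passed"]
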