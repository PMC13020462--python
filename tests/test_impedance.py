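"""Transfer impedance, sensitivity fields, regional maps, analytic oracles."""

import math

import numpy as np
import pytest

from thoraxfem import (SolveSpec, assemble_system,
                       halfspace_point_electrode_Z, planar_sensitivity_map,
                       regional_contribution, sensitivity_field,
                       solve_injection, solve_tetrapolar,
                       transfer_impedance_integral,
                       transfer_impedance_voltage, uniform_table)

RHO_SOFT = 1.0 / 0.18233


def _square(s):
    return {"A": [-s / 2, -s / 2, 0], "B": [-s / 2, s / 2, 0],
            "C": [s / 2, -s / 2, 0], "D": [s / 2, s / 2, 0]}


class TestHalfspaceFormula:
    def test_square_adjacent_edge_drive(self):
        s = 0.08
        Z = halfspace_point_electrode_Z(_square(s), RHO_SOFT)
        closed = RHO_SOFT * (1 - 1 / math.sqrt(2)) / (math.pi * s)
        assert Z == pytest.approx(closed, rel=1e-12)
        assert Z == pytest.approx(6.39, abs=0.01)

    def test_wenner_collinear(self):
        a = 0.05
        pos = {"A": [0, 0, 0], "C": [a, 0, 0], "D": [2 * a, 0, 0],
               "B": [3 * a, 0, 0]}
        assert halfspace_point_electrode_Z(pos, 2.0) == pytest.approx(
            2.0 / (2 * math.pi * a), rel=1e-12)

    def test_diagonal_drive_is_null(self):
        s = 0.08
        pos = {"A": [-s / 2, -s / 2, 0], "B": [s / 2, s / 2, 0],
               "C": [s / 2, -s / 2, 0], "D": [-s / 2, s / 2, 0]}
        assert halfspace_point_electrode_Z(pos, 5.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_coincident_points_rejected(self):
        pos = _square(0.08)
        pos["C"] = pos["A"]
        with pytest.raises(ValueError, match="coincide"):
            halfspace_point_electrode_Z(pos, 1.0)


class TestSensitivityField:
    def test_definition_identity(self, coarser_result):
        r = coarser_result
        kappa = r.sol_AB.system.kappa
        manual = np.einsum("ij,ij->i", r.sol_AB.J, r.sol_CD.J) / (
            kappa * 1e-3**2)
        assert np.allclose(r.field.z, manual)

    def test_negative_sensitivity_regions_exist(self, coarser_result):
        z = coarser_result.field.z
        assert (z < 0).any() and (z > 0).any()

    def test_dual_methods_agree(self, coarser_result):
        Zi = coarser_result.Z_integral.Z
        Zv = coarser_result.Z_voltage.Z
        assert abs(Zi - Zv) / Zv < 0.02   # P1 duality: machine-level here
        assert abs(Zi - Zv) / Zv < 1e-9

    def test_mismatched_currents_rejected(self, small_cylinder):
        mesh, _ = small_cylinder
        tbl = uniform_table(0.5)
        a = solve_injection(assemble_system(mesh, tbl, SolveSpec(I0=1e-3)),
                            "electrode_A", "electrode_B")
        b = solve_injection(assemble_system(mesh, tbl, SolveSpec(I0=2e-3)),
                            "electrode_A", "electrode_B")
        with pytest.raises(ValueError, match="current"):
            sensitivity_field(a, b)

    def test_bipolar_power_dissipation_identity(self, small_cylinder):
        # with drive pair doubling as sense pair the integral reduces to
        # the dissipated power over I^2, i.e. the two-terminal resistance
        _, system = small_cylinder
        sol = solve_injection(system, "electrode_A", "electrode_B")
        fld = sensitivity_field(sol, sol)
        R = 0.10 / (0.5 * math.pi * 0.03**2)
        Z = transfer_impedance_integral(fld).Z
        assert Z == pytest.approx(R, rel=0.01)
        assert Z == pytest.approx(
            sol.electrode_potentials["electrode_A"].real / 1e-3, rel=1e-9)


class TestRegionalContribution:
    def test_partition_sums_to_total(self, coarser_result, coarser_mesh):
        total = sum(
            regional_contribution(coarser_result.field, coarser_mesh, name)
            for name in coarser_mesh.label_names.values())
        assert total == pytest.approx(coarser_result.Z_integral.Z,
                                      rel=1e-9)

    def test_ipsilateral_lung_dominates(self, coarser_result, coarser_mesh):
        right = regional_contribution(coarser_result.field, coarser_mesh,
                                      "lung_right")
        left = regional_contribution(coarser_result.field, coarser_mesh,
                                     "lung_left")
        assert right > left

    def test_empty_set_and_unknown_label(self, coarser_result,
                                         coarser_mesh):
        assert regional_contribution(coarser_result.field, coarser_mesh,
                                     []) == 0.0
        with pytest.raises(KeyError):
            regional_contribution(coarser_result.field, coarser_mesh,
                                  "liver")


class TestPlanarMaps:
    def test_plane_outside_mesh_rejected(self, coarser_result,
                                         right_geometry, coarser_mesh):
        with pytest.raises(ValueError, match="outside"):
            planar_sensitivity_map(coarser_result.field, coarser_mesh,
                                   right_geometry, depth=0.5)

    def test_map_masks_exterior(self, coarser_result, right_geometry,
                                coarser_mesh):
        pm = planar_sensitivity_map(coarser_result.field, coarser_mesh,
                                    right_geometry, 0.06)
        assert pm.n_inside > 0
        assert np.isnan(pm.values).any()
        assert np.isfinite(pm.average)

    def test_slab_riemann_sum_recovers_Z(self, coarser_result,
                                         right_geometry, coarser_mesh):
        # coarse slab-integration oracle: planar averages times slab
        # thickness, swept across the whole torso depth, rebuild Z
        sp, dz = 0.002, 0.0025
        total = 0.0
        for d in np.arange(-0.0175, 0.235, dz):
            try:
                pm = planar_sensitivity_map(coarser_result.field,
                                            coarser_mesh, right_geometry,
                                            d, spacing=sp)
            except ValueError:
                continue
            if np.isnan(pm.average):
                continue
            total += pm.average * pm.n_inside * sp * sp * dz
        assert total == pytest.approx(coarser_result.Z_integral.Z, rel=0.10)


class TestScalingLaws:
    def test_conductivity_scaling_inverse(self, coarser_mesh):
        # multiplying every admittivity by alpha divides Z by alpha
        alpha = 2.5
        from thoraxfem import PropertyTable, default_table

        base = default_table()
        scaled = PropertyTable(base.df.assign(
            sigma_S_per_m=base.df.sigma_S_per_m * alpha))
        Z0 = solve_tetrapolar(assemble_system(
            coarser_mesh, base, SolveSpec())).Z
        Z1 = solve_tetrapolar(assemble_system(
            coarser_mesh, scaled, SolveSpec())).Z
        assert Z1 == pytest.approx(Z0 / alpha, rel=1e-8)

    def test_voltage_reading_antisymmetric_in_sense_pair(
            self, coarser_result):
        fwd = transfer_impedance_voltage(
            coarser_result.sol_AB, ("electrode_C", "electrode_D"))
        rev = transfer_impedance_voltage(
            coarser_result.sol_AB, ("electrode_D", "electrode_C"))
        assert rev.Z_complex == pytest.approx(-fwd.Z_complex, rel=1e-12)
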