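"""Shared fixtures.

Heavy FEM artefacts (meshes, lead-field solves, sweeps) are session-scoped
and built lazily, so unit-test-only runs stay fast while the acceptance
tests share a single set of solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from thoraxfem import (FluidSpec, SolveSpec, assemble_system, build_geometry,
                       carve_fluid_region, cylinder_mesh, default_table,
                       fluid_volume_sweep, generate_mesh,
                       place_electrode_array, solve_tetrapolar,
                       vertical_sweep)

SIGMA_SOFT = 0.18233


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def right_geometry(geometry):
    return place_electrode_array(geometry, "right")


@pytest.fixture(scope="session")
def coarser_mesh(right_geometry):
    return generate_mesh(right_geometry, "coarser")


@pytest.fixture(scope="session")
def coarser_result(coarser_mesh, table):
    system = assemble_system(coarser_mesh, table, SolveSpec())
    return solve_tetrapolar(system)


@pytest.fixture(scope="session")
def level_results(right_geometry, table):
    """Tetrapolar solves at all four refinement levels (right lower pos)."""
    out = {}
    for lvl in ("coarser", "coarse", "normal", "fine"):
        mesh = generate_mesh(right_geometry, lvl)
        system = assemble_system(mesh, table, SolveSpec())
        result = solve_tetrapolar(system)
        entry = {"Z": result.Z, "n_tets": mesh.n_tets}
        if lvl in ("normal", "fine"):
            entry.update(mesh=mesh, result=result)
        else:                                   # keep memory bounded
            entry.update(mesh=None, result=None)
        out[lvl] = entry
    return out


@pytest.fixture(scope="session")
def t4_delta(geometry, level_results, table):
    """Baseline-minus-fluid Z for 300 mL in the right lower lobe (normal)."""
    g = carve_fluid_region(geometry, FluidSpec("right", 0.3e-3))
    g = place_electrode_array(g, "right")
    mesh = generate_mesh(g, "normal")
    Zf = solve_tetrapolar(assemble_system(mesh, table, SolveSpec())).Z
    return level_results["normal"]["Z"] - Zf


@pytest.fixture(scope="session")
def volume_sweeps(geometry):
    """Six-volume fluid sweeps on both sides at normal refinement."""
    return {side: fluid_volume_sweep(geometry, side, refinement="normal")
            for side in ("right", "left")}


@pytest.fixture(scope="session")
def vertical_sweeps(geometry):
    """Vertical sweeps for the trend checks (coarser refinement):
    per side, baseline plus ipsilateral and contralateral 670 mL fluid."""
    out = {}
    for side in ("right", "left"):
        other = "left" if side == "right" else "right"
        out[(side, None)] = vertical_sweep(geometry, side,
                                           refinement="coarser")
        out[(side, side)] = vertical_sweep(
            geometry, side, fluid=FluidSpec(side, 0.670e-3),
            refinement="coarser")
        out[(side, other)] = vertical_sweep(
            geometry, side, fluid=FluidSpec(other, 0.670e-3),
            refinement="coarser")
    return out


@pytest.fixture(scope="session")
def small_cylinder(table):
    """Homogeneous cylinder with end-cap electrodes, sigma = soft tissue."""
    from thoraxfem import uniform_table

    mesh = cylinder_mesh(0.03, 0.10, 0.006)
    system = assemble_system(mesh, uniform_table(0.5), SolveSpec())
    return mesh, system


@pytest.fixture(scope="session")
def unit_cube_system():
    """Unit-ish cube with full-face electrodes on z extremes."""
    from thoraxfem import box_mesh, uniform_table
    from thoraxfem.fem import assemble_system

    mesh = box_mesh((0.1, 0.1, 0.1), 0.02)
    # promote the z extremes to electrode patches
    cent = mesh.nodes[mesh.boundary_faces].mean(axis=1)
    mesh.face_labels[np.abs(cent[:, 2]) < 1e-12] = 1
    mesh.face_labels[np.abs(cent[:, 2] + 0.1) < 1e-12] = 2
    mesh.patch_names.update({1: "electrode_A", 2: "electrode_B"})
    system = assemble_system(mesh, uniform_table(0.5), SolveSpec())
    return mesh, system
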