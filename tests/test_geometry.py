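"""Synthetic thorax solids: volumes, fluid carving, electrode placement."""

import math

import numpy as np
import pytest

from thoraxfem import (FluidSpec, GeometryError, ThoraxParams,
                       build_geometry, carve_fluid_region,
                       place_electrode_array)


class TestBuildGeometry:
    def test_torso_volume_matches_target_exactly(self, geometry):
        # elliptic cylinder: pi*a*b*h is the closed-form oracle
        assert geometry.torso_volume() == pytest.approx(
            math.pi * geometry.torso_a * geometry.torso_b * geometry.height)
        assert geometry.torso_volume() == pytest.approx(23.4e-3, rel=1e-9)

    def test_lung_volume_hits_target_within_two_percent(self, geometry):
        assert geometry.lung_volume_total() == pytest.approx(
            4.84e-3, rel=0.02)

    def test_heart_volume_closed_form(self, geometry):
        a, b, c = geometry.params.heart_semi_axes
        assert geometry.heart_volume() == pytest.approx(
            4.0 / 3.0 * math.pi * a * b * c)

    def test_ribs_toggle_removes_region_only(self):
        bare = build_geometry(ThoraxParams(ribs_enabled=False))
        full = build_geometry(ThoraxParams())
        # same outer envelope
        assert bare.torso_a == pytest.approx(full.torso_a)
        assert bare.torso_b == pytest.approx(full.torso_b)
        pts = np.random.default_rng(0).uniform(
            [-0.15, -0.1, 0.0], [0.15, 0.1, 0.36], size=(20000, 3))
        pts = pts[bare.inside_torso(pts)]
        assert not np.any(bare.label_points(pts) == 4)
        assert np.any(full.label_points(pts) == 4)

    def test_infeasible_parameters_raise_descriptively(self):
        with pytest.raises(GeometryError, match="positive"):
            build_geometry(ThoraxParams(torso_height=-1.0))
        with pytest.raises(GeometryError, match="protrudes"):
            build_geometry(ThoraxParams(lung_semi_axes=(0.16, 0.12, 0.2)))

    def test_regions_disjoint_by_construction(self, geometry):
        pts = np.random.default_rng(1).uniform(
            [-0.16, -0.11, 0.0], [0.16, 0.11, 0.38], size=(50000, 3))
        pts = pts[geometry.inside_torso(pts)]
        labels = geometry.label_points(pts)
        heart = geometry._in_heart(pts)
        # every heart-solid point is labelled heart (precedence)
        assert np.all(labels[heart & geometry.inside_domain(pts)] == 3)

    def test_build_is_cached_and_deterministic(self):
        assert build_geometry() is build_geometry()


class TestFluidCarving:
    def test_reference_volume_realized_within_one_percent(self, geometry):
        g = carve_fluid_region(geometry, FluidSpec("right", 0.670e-3))
        spec = g.fluid["right"]
        assert spec.realized_volume == pytest.approx(0.670e-3, rel=0.01)
        assert spec.cut_height > geometry.lung_base_height("right")

    def test_zero_target_returns_identical_geometry(self, geometry):
        assert carve_fluid_region(geometry, FluidSpec("left", 0.0)) \
            is geometry

    def test_cut_height_monotone_in_volume(self, geometry):
        cuts = [carve_fluid_region(geometry, FluidSpec("right", v))
                .fluid["right"].cut_height
                for v in (0.1e-3, 0.3e-3, 0.6e-3)]
        assert cuts[0] < cuts[1] < cuts[2]

    def test_bisection_against_tabulated_profile(self, geometry):
        # independent check: realized volume recomputed from the height
        # profile at the returned cut equals the target
        g = carve_fluid_region(geometry, FluidSpec("left", 0.25e-3))
        cut = g.fluid["left"].cut_height
        assert geometry.lung_volume_below("left", cut) == pytest.approx(
            0.25e-3, rel=0.01)

    def test_overlarge_target_fails(self, geometry):
        big = 0.95 * geometry.lung_volume("right")
        with pytest.raises(GeometryError, match="90%"):
            carve_fluid_region(geometry, FluidSpec("right", big))

    def test_fluid_is_subset_of_lung(self, geometry):
        g = carve_fluid_region(geometry, FluidSpec("right", 0.4e-3))
        pts = np.random.default_rng(2).uniform(
            [-0.16, -0.11, 0.0], [0.0, 0.11, 0.30], size=(30000, 3))
        pts = pts[g.inside_torso(pts)]
        labels = g.label_points(pts)
        fluid = labels == 5
        assert fluid.any()
        assert np.all(g._in_lung_solid(pts[fluid], "right"))
        assert np.all(pts[fluid, 2] < g.fluid["right"].cut_height)


class TestElectrodePlacement:
    def test_bottom_row_level_with_lung_base(self, geometry):
        g = place_electrode_array(geometry, "right")
        base = geometry.lung_base_height("right")
        zs = sorted(z for _, _, z in g.electrode_array.centers)
        assert zs[0] == pytest.approx(base, abs=2e-3)
        assert zs[1] == pytest.approx(base, abs=2e-3)

    def test_offset_is_rigid_translation(self, geometry):
        g0 = place_electrode_array(geometry, "right", vertical_offset=0.0)
        g2 = place_electrode_array(geometry, "right", vertical_offset=0.02)
        for (l0, w0, z0), (l2, w2, z2) in zip(g0.electrode_array.centers,
                                              g2.electrode_array.centers):
            assert l0 == l2 and w0 == pytest.approx(w2)
            assert z2 - z0 == pytest.approx(0.02)

    def test_square_in_unrolled_metric(self, geometry):
        g = place_electrode_array(geometry, "left", separation=0.08)
        c = {lab: np.array([w, z]) for lab, w, z in
             g.electrode_array.centers}
        # A-B and C-D are the vertical edges, A-C and B-D the horizontal
        for pair in (("A", "B"), ("C", "D"), ("A", "C"), ("B", "D")):
            d = np.linalg.norm(c[pair[0]] - c[pair[1]])
            assert d == pytest.approx(0.08, abs=1e-9)

    def test_placement_off_surface_fails(self, geometry):
        with pytest.raises(GeometryError, match="falls off"):
            place_electrode_array(geometry, "right", separation=0.5)
        with pytest.raises(GeometryError, match="falls off"):
            place_electrode_array(geometry, "right", vertical_offset=0.5)

    def test_bad_corner_assignment_rejected(self, geometry):
        with pytest.raises(GeometryError, match="corner_assignment"):
            place_electrode_array(
                geometry, "right",
                corner_assignment={"A": "TL", "B": "TL", "C": "TR",
                                   "D": "BR"})
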