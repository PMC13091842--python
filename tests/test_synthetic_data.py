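import numpy as np
import pytest

from sgmech.apposition import distance_map, gapp_overall, gapp_profile
from sgmech.errors import ParameterError
from sgmech.synthetic_data import (DeploySpec, VesselSpec,
                                   kinematic_deploy, laplace_stress_field,
                                   lobe_area_fraction, lobe_within_fraction,
                                   make_contact_field, make_vessel,
                                   perturb_stent)
from sgmech.device_geometry import RingSpec, assemble_device, build_graft


class TestMakeVessel:
    def test_cylinder_area_and_centerline(self):
        mesh, cl = make_vessel(VesselSpec(kind="cylinder", diameter=30.0,
                                          length=100.0), 1.0)
        assert mesh.area() == pytest.approx(3000 * np.pi, rel=5e-3)
        assert cl.length == pytest.approx(100.0)
        assert mesh.thickness == 1.8

    def test_torus_centerline_arc(self):
        mesh, cl = make_vessel(VesselSpec(kind="torus_segment",
                                          diameter=30.0, bend_radius=50.0,
                                          arc_deg=90.0), 1.0)
        assert cl.length == pytest.approx(25 * np.pi, rel=1e-3)

    def test_taper_mid_diameter(self):
        mesh, _ = make_vessel(VesselSpec(kind="tapered", diameter=34.0,
                                         diameter_distal=28.0,
                                         length=100.0), 1.0)
        mid = mesh.nodes[np.abs(mesh.nodes[:, 2] - 50.0) < 0.6]
        d_mid = 2 * np.hypot(mid[:, 0], mid[:, 1]).mean()
        assert d_mid == pytest.approx(31.0, abs=0.1)

    def test_coarse_element_rejected(self):
        with pytest.raises(ParameterError):
            make_vessel(VesselSpec(kind="cylinder", diameter=30.0,
                                   length=50.0), 10.0)


class TestKinematicDeploy:
    def _device(self, diameter):
        graft = build_graft(diameter, 40.0, 1.0)
        rings = [RingSpec(diameter, 5, 7.5, 0.5, axial_position=z)
                 for z in (10.0, 30.0)]
        return assemble_device(rings, graft, suture_spacing=1.0,
                               working_range=(27.0, 32.0))

    def test_matched_device_full_apposition(self, straight_vessel):
        spec, wall, cl = straight_vessel
        dspec = DeploySpec(self._device(30.0), spec,
                           landing_arc_length=10.0, fold_count=0,
                           fold_depth=0.0, gap_params={"value": 0.0})
        deployed, truth = kinematic_deploy(dspec, wall, cl)
        assert truth["overall_within_fraction"] == pytest.approx(1.0)
        d = distance_map(deployed.graft, wall)
        assert gapp_overall(d, deployed.graft.element_areas()) \
            == pytest.approx(100.0)

    def test_constant_2mm_gap_zero_gapp(self, straight_vessel):
        spec, wall, cl = straight_vessel
        dspec = DeploySpec(self._device(30.0), spec,
                           landing_arc_length=10.0, fold_count=0,
                           fold_depth=0.0, gap_params={"value": 2.0})
        deployed, truth = kinematic_deploy(dspec, wall, cl)
        assert truth["overall_within_fraction"] == 0.0
        d = distance_map(deployed.graft, wall)
        assert gapp_overall(d, deployed.graft.element_areas()) \
            == pytest.approx(0.0)

    def test_lobe_fraction_closed_form_vs_dense_sampling(self):
        """The quadrature area fraction matches a dense point-sampling
        estimate of the exact lobe profile."""
        gap, depth, r_base, k, thr = 0.3, 3.0, 14.7, 4, 1.0
        analytic = lobe_area_fraction(gap, depth, thr, r_base, k)
        u = np.linspace(0, 2 * np.pi, 2_000_001)
        r = r_base - depth / 2 * (1 - np.cos(u))
        w = np.sqrt(r**2 + (depth * k / 2 * np.sin(u))**2)
        dist = gap + depth / 2 * (1 - np.cos(u))
        sampled = np.sum(w * (dist < thr)) / np.sum(w)
        assert analytic == pytest.approx(sampled, abs=1e-4)
        # the angular fraction is the k-independent arccos form
        assert lobe_within_fraction(gap, depth, thr) == pytest.approx(
            np.arccos(1 - 2 * (thr - gap) / depth) / np.pi)

    def test_oversized_device_matches_ground_truth(self, fold_deployment):
        dspec, wall, cl = fold_deployment
        deployed, truth = kinematic_deploy(dspec, wall, cl)
        prof = gapp_profile(deployed.graft, wall, cl)
        overall_truth = 100 * truth["overall_within_fraction"]
        assert prof.overall_gapp == pytest.approx(overall_truth, abs=1.0)

    def test_self_intersection_rejected(self, straight_vessel):
        spec, wall, cl = straight_vessel
        dspec = DeploySpec(self._device(34.0), spec,
                           landing_arc_length=10.0, fold_count=4,
                           fold_depth=16.0, gap_params={"value": 0.0})
        with pytest.raises(ParameterError, match="self-intersection"):
            kinematic_deploy(dspec, wall, cl)

    def test_device_must_fit(self, straight_vessel):
        spec, wall, cl = straight_vessel
        dspec = DeploySpec(self._device(30.0), spec,
                           landing_arc_length=90.0)
        with pytest.raises(ParameterError, match="fit"):
            kinematic_deploy(dspec, wall, cl)


class TestContactField:
    def test_planted_sums_and_fractions(self):
        regions = np.repeat([0, 1, 2], 100)
        cf, book = make_contact_field(regions, [10.0, 25.0, 0.0],
                                      [0.5, 0.3, 0.1], seed=11)
        mags = cf.magnitudes()
        for rid, expected in enumerate([10.0, 25.0, 0.0]):
            m = (regions[cf.node_index] == rid)
            assert mags[m].sum() == pytest.approx(expected, abs=1e-9)
        assert book["regions"][0]["contact_nodes"] == 50

    def test_seed_changes_nodes_not_sums(self):
        regions = np.repeat([0, 1], 200)
        a, _ = make_contact_field(regions, [7.0, 3.0], [0.25, 0.25], seed=1)
        b, _ = make_contact_field(regions, [7.0, 3.0], [0.25, 0.25], seed=2)
        assert not np.array_equal(a.node_index, b.node_index)
        for field in (a, b):
            assert field.magnitudes().sum() == pytest.approx(10.0, abs=1e-9)

    def test_same_seed_reproducible(self):
        regions = np.repeat([0, 1], 50)
        a, _ = make_contact_field(regions, [4.0, 2.0], [0.5, 0.5], seed=9)
        b, _ = make_contact_field(regions, [4.0, 2.0], [0.5, 0.5], seed=9)
        np.testing.assert_array_equal(a.node_index, b.node_index)
        np.testing.assert_array_equal(a.values, b.values)

    def test_positive_sum_needs_contact(self):
        regions = np.zeros(10, dtype=int)
        with pytest.raises(ParameterError):
            make_contact_field(regions, [5.0], [0.01], seed=0)


class TestLaplace:
    def test_hand_computation(self):
        spec = VesselSpec(kind="cylinder", diameter=30.0, length=50.0)
        mesh, _ = make_vessel(spec, 2.0)
        f = laplace_stress_field(spec, mesh)
        p = 80 * 133.322e-6
        np.testing.assert_allclose(f.values[:, 0], p * 15 / 1.8, atol=1e-6)
        np.testing.assert_allclose(f.values[:, 1], p * 15 / 3.6, atol=1e-6)

    def test_zero_pressure_and_thickness_scaling(self):
        base = VesselSpec(kind="cylinder", diameter=30.0, length=50.0)
        mesh, _ = make_vessel(base, 2.0)
        zero = laplace_stress_field(
            VesselSpec(kind="cylinder", diameter=30.0, length=50.0,
                       pressure=0.0), mesh)
        assert np.all(zero.values == 0.0)
        thick = laplace_stress_field(
            VesselSpec(kind="cylinder", diameter=30.0, length=50.0,
                       wall_thickness=3.6), mesh)
        ref = laplace_stress_field(base, mesh)
        np.testing.assert_allclose(thick.values, ref.values / 2, atol=1e-12)

    def test_non_cylinder_rejected(self):
        spec = VesselSpec(kind="torus_segment", diameter=20.0,
                          bend_radius=60.0, arc_deg=90.0)
        mesh, _ = make_vessel(spec, 2.0)
        with pytest.raises(ParameterError):
            laplace_stress_field(spec, mesh)


class TestPerturbStent:
    def test_unit_scales_plant_zero_errors(self, crown_ring):
        _, planted = perturb_stent(crown_ring, [1.0] * 5)
        assert planted == [0.0] * 5

    def test_known_scale_plants_s2_minus_1(self, crown_ring):
        _, planted = perturb_stent(crown_ring, [1.02] * 5)
        np.testing.assert_allclose(planted, 4.04, atol=1e-9)

    def test_deterministic_given_seed(self, crown_ring):
        a, pa = perturb_stent(crown_ring, {"low": 0.9, "high": 1.1}, seed=3)
        b, pb = perturb_stent(crown_ring, {"low": 0.9, "high": 1.1}, seed=3)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        assert pa == pb

    def test_bad_scales_rejected(self, crown_ring):
        with pytest.raises(ParameterError):
            perturb_stent(crown_ring, [1.0, 1.0])  # wrong length
        with pytest.raises(ParameterError):
            perturb_stent(crown_ring, [-1.0] * 5)
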