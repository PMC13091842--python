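import numpy as np
import pytest

from sgmech.apposition import (AppositionConfig, distance_map, gapp_overall,
                               gapp_profile, point_triangle_distance)
from sgmech.device_geometry import build_graft
from sgmech.errors import ParameterError
from sgmech.mesh_core import Centerline, TriMesh
from sgmech.synthetic_data import VesselSpec, make_vessel


@pytest.fixture(scope="module")
def wall30():
    spec = VesselSpec(kind="cylinder", diameter=30.0, length=100.0)
    return make_vessel(spec, element_size=1.0)


class TestDistanceMap:
    def test_concentric_offset(self, wall30):
        wall, _ = wall30
        graft = build_graft(29.0, 80.0, 1.0)
        graft.nodes[:, 2] += 10.0
        d = distance_map(graft, wall)
        # mesh faceting bounds the deviation from the exact 0.5 mm offset
        # by the chord sagitta of 1 mm elements on a 15 mm radius (~8e-3)
        np.testing.assert_allclose(d, 0.5, atol=1e-2)

    def test_coincident_surfaces_zero(self, wall30):
        wall, _ = wall30
        sub = TriMesh(wall.nodes.copy(), wall.triangles[:200].copy())
        d = distance_map(sub, wall)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_matches_bruteforce_minimum(self):
        """Random probes against an irregular wall equal the exhaustive
        all-triangle nearest distance to machine precision."""
        rng = np.random.default_rng(5)
        wall = TriMesh(rng.normal(scale=10, size=(60, 3)),
                       rng.integers(0, 60, size=(80, 3)))
        wall = TriMesh(wall.nodes,
                       wall.triangles[wall.element_areas() > 1e-6])
        probes = TriMesh(rng.normal(scale=12, size=(30, 3)),
                         np.arange(30).reshape(10, 3))
        d = distance_map(probes, wall)
        brute = point_triangle_distance(probes.element_centroids(),
                                        wall.triangle_coords()).min(axis=1)
        np.testing.assert_allclose(d, brute, atol=1e-9)

    def test_empty_wall_rejected(self, wall30):
        wall, _ = wall30
        with pytest.raises(ParameterError):
            distance_map(wall, TriMesh(np.zeros((0, 3)),
                                       np.zeros((0, 3), dtype=int)))


class TestPointTriangle:
    def test_known_configurations(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
        cases = [
            ([0.25, 0.25, 1.0], 1.0),          # above interior
            ([2.0, 0.0, 0.0], 1.0),            # beyond a vertex
            ([0.5, -1.0, 0.0], 1.0),           # beside an edge
            ([1.0, 1.0, 0.0], np.sqrt(2) / 2),  # past the diagonal
            ([0.2, 0.3, 0.0], 0.0),            # inside, in-plane
        ]
        for p, expected in cases:
            d = point_triangle_distance(np.array([p]), tri)[0, 0]
            assert d == pytest.approx(expected, abs=1e-12)


class TestGappOverall:
    def test_all_within(self):
        assert gapp_overall(np.full(10, 0.5), np.ones(10)) == 100.0

    def test_boundary_is_strict(self):
        cfg = AppositionConfig(threshold=1.0, strict=True)
        assert gapp_overall(np.full(10, 1.0), np.ones(10), cfg) == 0.0
        loose = AppositionConfig(threshold=1.0, strict=False)
        assert gapp_overall(np.full(10, 1.0), np.ones(10), loose) == 100.0

    def test_area_weighting(self):
        d = np.array([0.5, 2.0])
        a = np.array([37.0, 63.0])
        assert gapp_overall(d, a) == pytest.approx(37.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            gapp_overall(np.array([0.5]), np.array([0.0]))

    def test_monotone_in_threshold(self, fold_deployment):
        from sgmech.synthetic_data import kinematic_deploy
        dspec, wall, cl = fold_deployment
        deployed, _ = kinematic_deploy(dspec, wall, cl)
        d = distance_map(deployed.graft, wall)
        areas = deployed.graft.element_areas()
        vals = [gapp_overall(d, areas, AppositionConfig(threshold=t))
                for t in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) >= 0)


class TestGappProfile:
    def _profile(self, graft_diam, wall30, gap_kind="uniform"):
        wall, cl = wall30
        graft = build_graft(graft_diam, 60.0, 1.0)
        graft.nodes[:, 2] += 20.0
        return graft, wall, cl

    def test_uniform_gap_all_sections_full(self, wall30):
        graft, wall, cl = self._profile(29.0, wall30)
        prof = gapp_profile(graft, wall, cl)
        populated = prof.section_gapp[~np.isnan(prof.section_gapp)]
        np.testing.assert_allclose(populated, 100.0)
        assert prof.window_stats["proximal_avg_pct"] == pytest.approx(100.0)
        assert prof.window_stats["distal_max_pct"] == pytest.approx(100.0)

    def test_step_gap_splits_windows(self, wall30):
        wall, cl = wall30
        graft = build_graft(29.0, 60.0, 1.0)
        graft.nodes[:, 2] += 20.0
        # inflate the distal half inward to a 2 mm gap
        distal = graft.nodes[:, 2] >= 50.0
        xy = graft.nodes[distal, :2]
        r = np.linalg.norm(xy, axis=1, keepdims=True)
        graft.nodes[distal, :2] = xy / r * 13.0
        prof = gapp_profile(graft, wall, cl)
        assert prof.window_stats["proximal_avg_pct"] == pytest.approx(100.0)
        assert prof.window_stats["distal_avg_pct"] == pytest.approx(0.0)

    def test_taper_crossover_position(self, wall30):
        """A linearly tapering gap crosses the 1 mm threshold within one
        section of the analytic crossing."""
        wall, cl = wall30
        graft = build_graft(29.0, 60.0, 1.0)
        graft.nodes[:, 2] += 20.0
        z = graft.nodes[:, 2]
        # gap grows 0.2 -> 2.2 mm over 60 mm: crosses 1.0 at z-20 = 24
        gap = 0.2 + 2.0 * (z - 20.0) / 60.0
        xy = graft.nodes[:, :2]
        r = np.linalg.norm(xy, axis=1, keepdims=True)
        graft.nodes[:, :2] = xy / r * (15.0 - gap[:, None])
        prof = gapp_profile(graft, wall, cl)
        crossing = prof.section_positions[
            np.nanargmax(prof.section_gapp < 50.0)]
        assert abs(crossing - 24.0) <= 1.5

    def test_section_area_weighted_mean_equals_overall(self, wall30):
        from sgmech.synthetic_data import kinematic_deploy
        wall, cl = wall30
        graft = build_graft(29.0, 60.0, 1.0)
        graft.nodes[:, 2] += 20.0
        prof = gapp_profile(graft, wall, cl)
        ok = ~np.isnan(prof.section_gapp)
        mean = np.average(prof.section_gapp[ok],
                          weights=prof.section_areas[ok])
        assert mean == pytest.approx(prof.overall_gapp, abs=1e-9)

    def test_rigid_motion_invariance(self, wall30):
        wall, cl = wall30
        graft = build_graft(28.5, 40.0, 1.5)
        graft.nodes[:, 2] += 30.0
        ref = gapp_profile(graft, wall, cl)
        ang = 0.6
        R = np.array([[1, 0, 0],
                      [0, np.cos(ang), -np.sin(ang)],
                      [0, np.sin(ang), np.cos(ang)]], dtype=float)
        t = np.array([3.0, -2.0, 7.0])
        g2 = TriMesh(graft.nodes @ R.T + t, graft.triangles.copy())
        w2 = TriMesh(wall.nodes @ R.T + t, wall.triangles.copy())
        c2 = Centerline(cl.points @ R.T + t, cl.arc_length.copy())
        moved = gapp_profile(g2, w2, c2)
        assert moved.overall_gapp == pytest.approx(ref.overall_gapp,
                                                   abs=1e-9)
        np.testing.assert_allclose(moved.section_gapp, ref.section_gapp,
                                   atol=1e-9)

    def test_proximal_offset_shifts_positions(self, wall30):
        wall, cl = wall30
        graft = build_graft(29.0, 40.0, 1.5)
        graft.nodes[:, 2] += 20.0
        base = gapp_profile(graft, wall, cl)
        shifted = gapp_profile(graft, wall, cl,
                               AppositionConfig(proximal_offset=5.0))
        np.testing.assert_allclose(shifted.section_positions,
                                   base.section_positions + 5.0)
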