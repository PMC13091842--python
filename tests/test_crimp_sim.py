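import numpy as np
import pytest
from dataclasses import replace

from sgmech.crimp_sim import (CrimpProtocol, CrossSection, RadialForceCurve,
                              calibrate, crimp_device, crimp_ring,
                              working_range_metrics)
from sgmech.device_geometry import RingSpec, assemble_device, build_graft
from sgmech.errors import ParameterError

RING = RingSpec(34.0, 5, 7.5, 0.5)
PROTO = CrimpProtocol(34.0, 16.0, 40)


def elastic_like(p):
    """Plateaus lifted far above any reachable stress: pure elasticity."""
    return replace(p, sigma_SL=5000.0, sigma_EL=5100.0,
                   sigma_SU=4000.0, sigma_EU=3000.0)


class TestCrossSection:
    def test_weights_sum_to_section_area(self):
        for n in (5, 9, 15):
            sec = CrossSection(0.5, n)
            assert sec.area == pytest.approx(np.pi * 0.25**2, abs=1e-9)

    def test_inertia_close_to_circular_section(self):
        sec = CrossSection(0.5, 31)
        assert sec.inertia() == pytest.approx(np.pi * 0.5**4 / 64, rel=1e-3)

    def test_too_few_fibres(self):
        with pytest.raises(ParameterError):
            CrossSection(0.5, 3)


class TestCrimpRing:
    def test_elastic_limit_zero_hysteresis(self, vc_params):
        c = crimp_ring(RING, elastic_like(vc_params), protocol=PROTO)
        dl, fl = c.branch("loading")
        du, fu = c.branch("unloading")
        match = {d: f for d, f in zip(dl, fl)}
        assert all(abs(match[d] - f) < 1e-6 for d, f in zip(du, fu))
        assert c.loop_area() == pytest.approx(0.0, abs=1e-9)

    def test_superelastic_dissipates(self, vc_params):
        c = crimp_ring(RING, vc_params, protocol=PROTO)
        assert c.loop_area() > 0
        dl, fl = c.branch("loading")
        du, fu = c.branch("unloading")
        grid = np.linspace(16.5, 33.5, 30)
        fl_i = np.interp(grid, dl[::-1], fl[::-1])
        fu_i = np.interp(grid, du, fu)
        assert np.all(fu_i <= fl_i + 1e-9)

    def test_force_vanishes_at_start_diameter(self, vc_params):
        c = crimp_ring(RING, vc_params, protocol=PROTO)
        dl, fl = c.branch("loading")
        assert fl[0] == pytest.approx(0.0, abs=1e-9)

    def test_shallower_crimp_smaller_loop(self, vc_params):
        deep = crimp_ring(RING, vc_params,
                          protocol=CrimpProtocol(34.0, 16.0, 40))
        shallow = crimp_ring(RING, vc_params,
                             protocol=CrimpProtocol(34.0, 25.0, 40))
        assert shallow.loop_area() < deep.loop_area()

    def test_step_refinement_convergence(self, vc_params):
        c1 = crimp_ring(RING, vc_params,
                        protocol=CrimpProtocol(34.0, 16.0, 30))
        c4 = crimp_ring(RING, vc_params,
                        protocol=CrimpProtocol(34.0, 16.0, 120))
        grid = np.linspace(16.5, 33.5, 25)
        for name in ("loading", "unloading"):
            d1, f1 = c1.branch(name)
            d4, f4 = c4.branch(name)
            o1, o4 = np.argsort(d1), np.argsort(d4)
            a = np.interp(grid, d1[o1], f1[o1])
            b = np.interp(grid, d4[o4], f4[o4])
            assert np.allclose(a, b, rtol=0.01, atol=0.02)

    def test_infeasible_target_rejected(self, vc_params):
        with pytest.raises(ParameterError, match="feasibility|fibre strain"):
            crimp_ring(RING, vc_params,
                       protocol=CrimpProtocol(34.0, 10.0, 20))


class TestCrimpDevice:
    def _device(self, k):
        rings = [RingSpec(34.0, 5, 7.5, 0.5, axial_position=10.0 + 18 * i)
                 for i in range(k)]
        graft = build_graft(34.0, 18.0 * k + 10, 1.5)
        return assemble_device(rings, graft, suture_spacing=3.0,
                               working_range=(29.0, 31.0))

    def test_additivity_of_identical_rings(self, vc_params):
        d3 = self._device(3)
        c3 = crimp_device(d3, vc_params, PROTO)
        c1 = crimp_ring(d3.rings[0], vc_params, protocol=PROTO)
        np.testing.assert_allclose(c3.forces, 3 * c1.forces, atol=1e-9)

    def test_ring_by_ring_recomputation(self, vc_params):
        dev = self._device(2)
        total = crimp_device(dev, vc_params, PROTO)
        manual = sum(crimp_ring(r, vc_params, protocol=PROTO).forces
                     for r in dev.rings)
        np.testing.assert_allclose(total.forces, manual, atol=1e-9)

    def test_empty_ring_list_zero_curve(self, vc_params):
        dev = self._device(1)
        dev.rings = []
        c = crimp_device(dev, vc_params, PROTO)
        assert np.all(c.forces == 0.0)

    def test_incompatible_diameter_errors(self, vc_params):
        dev = self._device(1)
        with pytest.raises(ParameterError, match="incompatible"):
            crimp_device(dev, vc_params, CrimpProtocol(40.0, 35.0, 20))


class TestWorkingRange:
    def _linear_curve(self):
        d = np.linspace(20.0, 35.0, 16)
        return RadialForceCurve(
            np.concatenate([d[::-1], d]),
            np.concatenate([(100 - 2 * d)[::-1], 100 - 2 * d]),
            np.array(["loading"] * 16 + ["unloading"] * 16))

    def test_closed_form_linear_branch(self):
        f28, f32, df = working_range_metrics(self._linear_curve(), 28, 32)
        assert (f28, f32, df) == pytest.approx((44.0, 36.0, 8.0))

    def test_flat_branch_zero_drop(self):
        d = np.linspace(20.0, 35.0, 16)
        c = RadialForceCurve(d, np.full(16, 7.0), np.array(["unloading"] * 16))
        assert working_range_metrics(c, 28, 32)[2] == pytest.approx(0.0)

    def test_interpolation_matches_dense_resample(self, vc_params):
        c = crimp_ring(RING, vc_params, protocol=PROTO)
        du, fu = c.branch("unloading")
        for d_lo, d_hi in [(28.0, 32.0), (20.0, 30.0)]:
            dense = np.union1d(np.linspace(du.min(), du.max(), 20001),
                               [d_lo, d_hi])
            fd = np.interp(dense, du, fu)
            f_lo, f_hi, _ = working_range_metrics(c, d_lo, d_hi)
            assert f_lo == pytest.approx(
                fd[np.searchsorted(dense, d_lo)], abs=1e-9)
            assert f_hi == pytest.approx(
                fd[np.searchsorted(dense, d_hi)], abs=1e-9)

    def test_window_outside_branch_errors(self):
        with pytest.raises(ParameterError):
            working_range_metrics(self._linear_curve(), 10.0, 15.0)


class TestCalibrate:
    def test_self_calibration_recovers_plateaus(self, vc_params):
        exp = crimp_ring(RING, vc_params, protocol=PROTO)
        start = replace(vc_params, sigma_SL=500.0, sigma_SU=400.0)
        fit, r2, info = calibrate(
            exp, start, ["sigma_SL", "sigma_SU"],
            {"sigma_SL": (450.0, 619.0), "sigma_SU": (300.0, 560.0)},
            RING, PROTO, seed=7)
        assert fit.sigma_SL == pytest.approx(550.0, rel=0.02)
        assert fit.sigma_SU == pytest.approx(450.0, rel=0.02)
        assert r2 > 0.99
        assert info["converged"]

    def test_zero_free_params_direct_r2(self, vc_params):
        exp = crimp_ring(RING, vc_params, protocol=PROTO)
        _, r2, info = calibrate(exp, vc_params, [], {}, RING, PROTO)
        assert r2 == pytest.approx(1.0)
        assert info["n_iter"] == 0

    def test_nonspanning_experimental_rejected(self, vc_params):
        exp = crimp_ring(RING, vc_params,
                         protocol=CrimpProtocol(34.0, 30.0, 20))
        with pytest.raises(ParameterError, match="span"):
            calibrate(exp, vc_params, [], {}, RING, PROTO)
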