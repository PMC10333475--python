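"""Reduced-order hemodynamics: losses, pulsatile solve, calibration."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from coarckit import hemodynamics as hd


class TestBernoulli:
    @pytest.mark.parametrize("vj,vp,mode,expected", [
        (2.0, 0.0, "simplified", 16.0),
        (1.0, 0.0, "full", 0.5 * 1050 / hd.MMHG),   # 525 Pa = 3.938 mmHg
        (1.7, 1.7, "simplified", 0.0),
        (1.7, 1.7, "full", 0.0),
    ])
    def test_examples(self, vj, vp, mode, expected):
        assert hd.bernoulli_gradient(vj, vp, mode) == pytest.approx(expected, abs=1e-9)

    def test_full_value_is_3_938(self):
        assert hd.bernoulli_gradient(1.0, mode="full") == pytest.approx(3.938, abs=1e-3)

    @given(st.floats(min_value=0.05, max_value=8.0))
    def test_simplified_to_full_ratio_is_constant(self, v):
        """4/ (rho/2/133.322) = 4/3.938... for every jet speed (identity)."""
        ratio = hd.bernoulli_gradient(v) / hd.bernoulli_gradient(v, mode="full")
        assert ratio == pytest.approx(4.0 / (0.5 * 1050 / hd.MMHG), rel=1e-12)

    @pytest.mark.parametrize("vj,vp", [(-1.0, 0.0), (1.0, 2.0), (1.0, -0.5)])
    def test_invalid_velocities_rejected(self, vj, vp):
        with pytest.raises(ValueError):
            hd.bernoulli_gradient(vj, vp)


class TestJetVelocity:
    def test_continuity(self):
        assert hd.jet_velocity(1.2, 4.0) == pytest.approx(4.8)
        assert hd.jet_velocity(1.2, 1.0) == pytest.approx(1.2)

    def test_inverse_query_anchors_proximal_range(self):
        # ratio that brings 1.2 m/s to 1.7 m/s
        ratio = 1.7 / 1.2
        assert ratio == pytest.approx(1.4167, abs=1e-4)
        assert hd.jet_velocity(1.2, ratio) == pytest.approx(1.7)

    def test_subunity_ratio_rejected(self):
        with pytest.raises(ValueError):
            hd.jet_velocity(1.2, 0.9)


class TestSegmentLoss:
    fluid = hd.FluidProps()

    def test_poiseuille_closed_form(self):
        seg = hd.VesselSegment("t", 0.1, 0.01, 0.01)
        Q = 1e-5
        expected = 128 * self.fluid.viscosity * 0.1 * Q / (np.pi * 0.01**4)
        assert hd.segment_pressure_loss(seg, Q, 0.0, self.fluid) == \
            pytest.approx(expected, rel=1e-12)

    def test_inviscid_contracting_taper_is_bernoulli(self):
        seg = hd.VesselSegment("t", 0.1, 0.01, 0.007)
        Q = 1e-5
        inviscid = hd.FluidProps(viscosity=1e-15)
        vd, vp = Q / seg.area(0.1), Q / seg.area(0.0)
        assert hd.segment_pressure_loss(seg, Q, 0.0, inviscid) == \
            pytest.approx(0.5 * 1050 * (vd**2 - vp**2), rel=1e-9)

    def test_zero_flow_zero_loss(self):
        seg = hd.VesselSegment("t", 0.1, 0.01, 0.007,
                               stenosis=hd.Stenosis(area_ratio=0.3))
        assert hd.segment_pressure_loss(seg, 0.0, 0.0, self.fluid) == 0.0

    def test_stenosis_terms_hand_computed(self):
        seg = hd.VesselSegment("t", 0.02, 0.007, 0.007,
                               stenosis=hd.Stenosis(area_ratio=0.25, length=0.008))
        Q, mu, rho = 3e-5, self.fluid.viscosity, self.fluid.density
        plain = hd.segment_pressure_loss(
            hd.VesselSegment("t", 0.02, 0.007, 0.007), Q, 0.0, self.fluid)
        got = hd.segment_pressure_loss(seg, Q, 0.0, self.fluid) - plain
        a0 = np.pi * 0.007**2 / 4
        v0 = Q / a0
        want = (32 * (0.008 / 0.007) * 16 * mu * v0 / 0.007
                + 0.5 * 1.52 * rho * 9.0 * v0 * abs(v0))
        assert got == pytest.approx(want, rel=1e-12)

    def test_loss_is_odd_like_in_flow_for_uniform_tube(self):
        seg = hd.VesselSegment("t", 0.1, 0.008, 0.008,
                               stenosis=hd.Stenosis(area_ratio=0.4))
        fwd = hd.segment_pressure_loss(seg, 2e-5, 0.0, self.fluid)
        rev = hd.segment_pressure_loss(seg, -2e-5, 0.0, self.fluid)
        assert rev == pytest.approx(-fwd, rel=1e-12)


def steady_bcs(v=0.3, p=80.0):
    return hd.BoundaryConditions(v_peak=v, waveform="constant", p_upper=p, p_lower=p)


class TestPulsatileSolve:
    def test_single_tube_matches_poiseuille(self):
        seg = hd.VesselSegment("tube", 0.2, 0.008, 0.008)
        net = hd.ArterialNetwork(main=[seg], branches=[])
        res = hd.solve_pulsatile(net, steady_bcs())
        Q = res.q_in[0]
        expected = 128 * 0.0035 * 0.2 * Q / (np.pi * 0.008**4)
        assert (res.p_in[-1] - 80 * hd.MMHG) == pytest.approx(expected, rel=0.005)

    def test_inviscid_contraction_matches_bernoulli(self):
        net = hd.ArterialNetwork(main=[hd.VesselSegment("c", 0.1, 0.01, 0.006)],
                                 branches=[])
        res = hd.solve_pulsatile(net, steady_bcs(), hd.FluidProps(viscosity=1e-10))
        Q = res.q_in[0]
        vd, vp = Q / net.main[0].area(0.1), Q / net.main[0].area(0.0)
        assert (res.p_in[-1] - 80 * hd.MMHG) == \
            pytest.approx(0.5 * 1050 * (vd**2 - vp**2), rel=0.005)

    def test_mass_conserved_to_1e10(self):
        res = hd.solve_pulsatile(hd.default_coa_network())
        assert res.mass_residual <= 1e-10

    def test_periodic_within_max_cycles(self):
        res = hd.solve_pulsatile(hd.default_coa_network())
        assert res.periodic and res.cycles <= 10

    def test_halving_dt_changes_peak_drop_below_one_percent(self):
        m1 = hd.extract_profiles(hd.solve_pulsatile(
            hd.default_coa_network())).metrics["transstenotic_dp_mmhg"]
        m2 = hd.extract_profiles(hd.solve_pulsatile(
            hd.default_coa_network(),
            settings=hd.SolverSettings(dt=0.0025))).metrics["transstenotic_dp_mmhg"]
        assert abs(m2 - m1) / m1 < 0.01

    def test_dt_must_divide_period(self):
        with pytest.raises(ValueError, match="dt"):
            hd.solve_pulsatile(hd.default_coa_network(),
                               settings=hd.SolverSettings(dt=0.003))

    def test_junction_continuity_enforced(self):
        with pytest.raises(ValueError, match="discontinuity"):
            hd.ArterialNetwork(main=[hd.VesselSegment("a", 0.05, 0.012, 0.012),
                                     hd.VesselSegment("b", 0.05, 0.008, 0.008)],
                               branches=[])


class TestProfiles:
    def test_unstenosed_network_pressure_monotone(self):
        net = hd.default_coa_network()
        net.main[3].stenosis = None
        res = hd.solve_pulsatile(net, steady_bcs(v=0.8, p=90.0))
        prof = hd.extract_profiles(res)
        assert np.all(np.diff(prof.p) <= 1e-9)

    def test_sharpest_drop_sits_in_the_throat(self, calibrated_case):
        prof = hd.extract_profiles(calibrated_case.result)
        lo, hi = prof.metrics["throat_span_mm"]
        assert lo <= prof.metrics["max_gradient_x_mm"] <= hi

    def test_reynolds_reported_and_flagged(self, calibrated_case):
        res = calibrated_case.result
        re = res.reynolds()
        assert set(re) >= {"ascending", "isthmus", "descending"}
        assert "isthmus" in res.laminar_violations()


class TestCalibration:
    def test_bernoulli_target_met(self, calibrated_case):
        assert calibrated_case.bernoulli_pspg == pytest.approx(57.2, abs=0.1)

    def test_recalibration_is_a_fixed_point(self, calibrated_case):
        again = hd.calibrate_stenosis(calibrated_case.network, target_pspg=57.2)
        assert again.area_ratio == pytest.approx(calibrated_case.area_ratio, abs=1e-3)

    def test_target_maps_monotonically_under_default_outlets(self, calibrated_case):
        """With arm/leg outlet pressures pinning the available drop, a larger
        Doppler target calibrates to a *larger* throat (see methods note)."""
        c45 = hd.calibrate_stenosis(hd.default_coa_network(), target_pspg=45.0)
        c70 = hd.calibrate_stenosis(hd.default_coa_network(), target_pspg=70.0)
        assert c45.area_ratio < calibrated_case.area_ratio < c70.area_ratio

    def test_open_throat_limit(self):
        """A target equal to the nearly-open gradient calibrates to a
        nearly-open throat (low-flow, equal-outlet configuration)."""
        bcs = hd.BoundaryConditions(v_peak=0.2, p_upper=100.0, p_lower=100.0)
        net = hd.default_coa_network(area_ratio=1.0 / 1.01)
        probe = hd.solve_pulsatile(net, bcs)
        g_open = hd.bernoulli_gradient(float(np.max(hd.throat_velocity(probe))))
        cal = hd.calibrate_stenosis(hd.default_coa_network(), bcs=bcs,
                                    target_pspg=g_open, tol_mmhg=0.02,
                                    bounds=(1.01, 50.0))
        assert 1.0 / cal.area_ratio < 1.6

    def test_unreachable_target_raises(self):
        bcs = hd.BoundaryConditions(v_peak=0.1, p_upper=100.0, p_lower=100.0)
        with pytest.raises(ValueError, match="unreachable"):
            hd.calibrate_stenosis(hd.default_coa_network(), bcs=bcs,
                                  target_pspg=500.0)

    def test_template_without_stenosis_rejected(self):
        net = hd.default_coa_network()
        net.main[3].stenosis = None
        with pytest.raises(ValueError, match="stenosis"):
            hd.calibrate_stenosis(net, target_pspg=57.2)


class TestCriteriaAndTypes:
    @pytest.mark.parametrize("pspg,coll,expected", [
        (57.2, False, True),     # the Doppler value of the simulated case
        (15.0, True, True),      # >10 mmHg with collaterals
        (15.0, False, False),
        (20.0, False, False),    # strict inequality at 20
        (10.0, True, False),
    ])
    def test_pspg_criteria(self, pspg, coll, expected):
        assert hd.pspg_criteria(pspg, coll) is expected

    def test_negative_pspg_rejected(self):
        with pytest.raises(ValueError):
            hd.pspg_criteria(-1.0)

    def test_type_invariants(self):
        with pytest.raises(ValueError):
            hd.FluidProps(density=-1)
        with pytest.raises(ValueError):
            hd.Stenosis(area_ratio=1.3)
        with pytest.raises(ValueError):
            hd.VesselSegment("x", 0.1, 0.01, 0.01, cells=2)
        with pytest.raises(ValueError):
            hd.BoundaryConditions(p_upper=400.0)
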