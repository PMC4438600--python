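import math

import numpy as np
import pytest

from dripfert.soil import SoilHydraulics
from dripfert.water import (
    IrrigationHardware,
    KcProfile,
    WaterState,
    WetBulb,
    bulb_volume,
    effective_rain,
    etc_dual,
    invert_bulb_volume,
    irrigation_decision,
    kc_interpolate,
    qirr_available,
    redistribution_flux,
    rescale_to_fc,
    runoff_cn,
    wet_bulb_dimensions,
    wrv_intersection,
)


@pytest.fixture
def hyd():
    return SoilHydraulics(
        theta_fc=0.30, theta_wp=0.12, theta_sat=0.45, theta_res=0.05,
        ks=25.0, vg_alpha=0.036, vg_n=1.56,
    )


class TestKcInterpolation:
    def test_mid_plateau(self):
        p = KcProfile()
        for dat in (p.t2, (p.t2 + p.t3) // 2, p.t3):
            assert kc_interpolate(dat, p)["kc"] == p.kc_mid

    def test_linear_development_midpoint(self):
        p = KcProfile()
        mid = (p.t1 + p.t2) // 2
        got = kc_interpolate(mid, p)["kc"]
        frac = (mid - p.t1) / (p.t2 - p.t1)
        assert got == pytest.approx(p.kc_ini + frac * (p.kc_mid - p.kc_ini))

    def test_mulch_modifies_kcb_and_ke(self):
        bare = kc_interpolate(60, KcProfile(mulch=False))
        mulched = kc_interpolate(60, KcProfile(mulch=True))
        assert mulched["kcb"] == pytest.approx(1.20 * bare["kcb"])
        assert mulched["ke"] == pytest.approx(0.35 * bare["ke"])

    def test_beyond_cycle_rejected(self):
        with pytest.raises(ValueError):
            kc_interpolate(KcProfile().t4 + 1, KcProfile())


class TestEtcDual:
    def test_mulched_full_cover_is_transpiration_only(self):
        r = etc_dual(5.0, kcb=1.0, ke=0.0, covered_fraction=0.8,
                     wet_surface_fraction=0.3)
        assert r["evaporation"] == 0.0
        assert r["etc"] == r["transpiration"]

    def test_nominal_form_at_unit_fractions(self):
        r = etc_dual(5.0, kcb=1.0, ke=0.4, covered_fraction=1.0,
                     wet_surface_fraction=1.0)
        assert r["etc"] == pytest.approx((1.0 + 0.4) * 5.0)

    def test_zero_et0_zero_etc(self):
        assert etc_dual(0.0, 1.0, 0.4, 0.5, 0.5)["etc"] == 0.0

    def test_single_kc_mode(self):
        r = etc_dual(5.0, kcb=0.0, ke=0.0, covered_fraction=0.5,
                     wet_surface_fraction=0.5, mode="single", kc=1.1)
        assert r["etc"] == pytest.approx(1.1 * 5.0 * 0.5)
        assert r["evaporation"] == 0.0


class TestWetBulbDimensions:
    def test_power_law_scaling_in_ks(self):
        xf1, zf1 = wet_bulb_dimensions(0.05, 1e-6, 1e-6)
        xf2, zf2 = wet_bulb_dimensions(0.05, 2e-6, 1e-6)
        assert xf2 / xf1 == pytest.approx(2.0**-0.17)
        assert zf2 / zf1 == pytest.approx(2.0**0.45)

    def test_zero_water_zero_bulb(self):
        assert wet_bulb_dimensions(0.0, 1e-6, 1e-6) == (0.0, 0.0)

    def test_hand_power_law_values(self):
        # Vw=0.05 m3, Ks/q = 1e6 m^-2
        xf, zf = wet_bulb_dimensions(0.05, 1.0, 1e-6)
        assert xf == pytest.approx(1.82 * 0.05**0.22 * 1e6**-0.17, rel=1e-12)
        assert zf == pytest.approx(2.54 * 0.05**0.63 * 1e6**0.45, rel=1e-12)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            wet_bulb_dimensions(0.05, 1e-6, 0.0)


class TestRescaleToFc:
    def test_shape_preserved(self):
        xf1, zf1 = rescale_to_fc(0.6, 0.4, 0.02, 0.30)
        assert zf1 / xf1 == pytest.approx(0.4 / 0.6)

    def test_mass_identity(self):
        for vw in (0.005, 0.02, 0.08):
            xf1, zf1 = rescale_to_fc(0.6, 0.4, vw, 0.30)
            assert bulb_volume(xf1, zf1) * 0.30 == pytest.approx(vw, rel=1e-9)

    def test_cube_root_scaling_in_volume(self):
        a = rescale_to_fc(0.6, 0.4, 0.02, 0.30)[0]
        b = rescale_to_fc(0.6, 0.4, 0.04, 0.30)[0]
        assert b / a == pytest.approx(2 ** (1 / 3))

    def test_inversion_recovers_target_dimension(self):
        vw = invert_bulb_volume(0.35, "zf1", 25.0, 5.56e-7, 0.30)
        from dripfert.water import make_bulb
        bulb = make_bulb(vw, 25.0, 5.56e-7, 0.30)
        assert bulb.zf1 == pytest.approx(0.35, abs=1e-6)


class TestWrvIntersection:
    def test_bulb_inside_erv_returns_bulb_volume(self):
        bulb = WetBulb(xf1=0.10, zf1=0.10, position=(0.0, 0.0))
        got = wrv_intersection(0.5, 0.5, 0.6, (0.0, 0.0), [bulb])
        assert got == pytest.approx(bulb.volume, rel=0.02)

    def test_disjoint_geometries_zero(self):
        bulb = WetBulb(xf1=0.1, zf1=0.2, position=(2.0, 0.0))
        assert wrv_intersection(0.4, 0.4, 0.5, (0.0, 0.0), [bulb]) == 0.0

    def test_grid_matches_monte_carlo(self):
        """Voxel integration vs a 10^6-point Monte-Carlo oracle, 2 %."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            rx = rng.uniform(0.2, 0.5)
            ry = rng.uniform(0.15, rx)
            rh = rng.uniform(0.2, 0.5)
            bx = rng.uniform(0.0, rx)
            bulb = WetBulb(xf1=rng.uniform(0.1, 0.4), zf1=rng.uniform(0.1, 0.5),
                           position=(bx, 0.0))
            grid = wrv_intersection(rx, ry, rh, (0.0, 0.0), [bulb])
            n = 1_000_000
            x = rng.uniform(bx - bulb.xf1, bx + bulb.xf1, n)
            y = rng.uniform(-bulb.xf1, bulb.xf1, n)
            z = rng.uniform(0, bulb.zf1, n)
            in_bulb = ((x - bx) / bulb.xf1) ** 2 + (y / bulb.xf1) ** 2 + (
                z / bulb.zf1) ** 2 <= 1
            in_erv = (x / rx) ** 2 + (y / ry) ** 2 + (z / rh) ** 2 <= 1
            box = (2 * bulb.xf1) ** 2 * bulb.zf1
            mc = float(np.mean(in_bulb & in_erv)) * box
            assert grid == pytest.approx(mc, rel=0.02)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            wrv_intersection(0.0, 0.1, 0.1, (0, 0), [])


class TestQirr:
    def test_literal_product(self):
        assert qirr_available(0.30, 0.10, 0.05) == pytest.approx(0.01)

    def test_linear_in_wrv(self):
        assert qirr_available(0.3, 0.1, 0.10) == pytest.approx(
            2 * qirr_available(0.3, 0.1, 0.05))

    def test_zero_volume(self):
        assert qirr_available(0.3, 0.1, 0.0) == 0.0


class TestRunoffCn:
    def test_below_initial_abstraction_no_runoff(self):
        assert runoff_cn(10.0, 75.0) == 0.0

    def test_cn100_returns_all_rain(self):
        assert runoff_cn(30.0, 100.0) == pytest.approx(30.0)

    def test_hand_arithmetic_cn75_p50(self):
        s = (1000 / 75 - 10) * 25.4
        expected = (50 - 0.2 * s) ** 2 / (50 + 0.8 * s)
        assert runoff_cn(50.0, 75.0) == pytest.approx(expected)
        assert runoff_cn(50.0, 75.0) == pytest.approx(9.29, abs=0.01)

    def test_cn_out_of_range(self):
        with pytest.raises(ValueError):
            runoff_cn(10.0, 0.0)


class TestEffectiveRain:
    def test_no_rain_all_zero(self):
        r = effective_rain(0.0, 0.0, 100.0)
        assert r["qrain"] == r["drainage"] == 0.0

    def test_saturated_soil_all_drains(self):
        r = effective_rain(10.0, 0.0, 0.0)
        assert r["qrain"] == 0.0
        assert r["drainage"] == pytest.approx(100.0)  # 10 mm -> m3/ha
        assert r["leach_trigger"]

    def test_ledger_partition(self):
        # 50 mm storm, 9.29 mm runoff, room for 300 m3/ha
        r = effective_rain(50.0, 9.29, 300.0)
        assert r["qrain"] == pytest.approx(300.0)
        assert r["drainage"] == pytest.approx((50 - 9.29) * 10 - 300.0)


class TestRedistribution:
    def test_no_gradient_no_flow(self, hyd):
        assert redistribution_flux(0.5, 0.5, 0.3, hyd, 10.0) == 0.0

    def test_antisymmetric_in_swap(self, hyd):
        q1 = redistribution_flux(0.8, 0.4, 0.3, hyd, 10.0)
        q2 = redistribution_flux(0.4, 0.8, 0.3, hyd, 10.0)
        assert q1 == pytest.approx(-q2)
        assert q1 > 0

    def test_never_overshoots_equalization(self, hyd):
        """One daily step must not invert the gradient (two-box oracle)."""
        for theta in np.linspace(0.15, 0.44, 10):
            q = redistribution_flux(0.9, 0.2, float(theta), hyd, 10.0)
            # moving q out of a volume-10 donor changes S by q/((ts-tr)*Ve)
            ds = q / ((hyd.theta_sat - hyd.theta_res) * 10.0)
            assert 0.9 - ds >= 0.2 + ds - 1e-12


class TestIrrigationDecision:
    def make_state(self, **kw):
        st = WaterState(
            w_erv=50.0, w_out=10.0, taw=100.0, raw=35.0, cap_erv=150.0,
            cap_out=30.0, v_erv=1000.0, v_wrv=600.0, v_out=200.0,
        )
        for k, v in kw.items():
            setattr(st, k, v)
        return st

    @pytest.fixture
    def hardware(self):
        return IrrigationHardware()

    def test_day_zero_always_irrigates(self, hyd, hardware):
        st = self.make_state(w_erv=100.0)  # no depletion
        d = irrigation_decision(st, "establishment", hyd, hardware, 0, 0.35,
                                0.2, 0.45, 0.3, False)
        assert d.irrigate

    def test_no_trigger_below_raw(self, hyd, hardware):
        st = self.make_state(w_erv=80.0)  # depletion 20 < raw 35
        d = irrigation_decision(st, "full_root", hyd, hardware, 10, 0.35,
                                0.45, 0.45, 0.3, False)
        assert not d.irrigate

    def test_ripening_never_irrigates(self, hyd, hardware):
        st = self.make_state(w_erv=0.0)
        d = irrigation_decision(st, "ripening", hyd, hardware, 100, 0.35,
                                0.45, 0.45, 0.3, False)
        assert not d.irrigate

    def test_nvz_caps_bulb_depth(self, hyd, hardware):
        st = self.make_state(w_erv=0.0, taw=3000.0, raw=1050.0)
        free = irrigation_decision(st, "full_root", hyd, hardware, 60, 0.35,
                                   0.45, 0.45, 0.3, False)
        capped = irrigation_decision(st, "full_root", hyd, hardware, 60, 0.35,
                                     0.45, 0.45, 0.3, True)
        assert capped.volume_net <= free.volume_net
        assert capped.constrained_by_nvz

    def test_duration_respects_max(self, hyd):
        hw = IrrigationHardware(max_irr_dur=0.5)
        st = self.make_state(w_erv=0.0, taw=5000.0, raw=1750.0)
        d = irrigation_decision(st, "full_root", hyd, hw, 60, 0.35,
                                0.45, 0.45, 0.3, False)
        assert d.duration_h <= 0.5 + 1e-9
        assert d.warnings
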