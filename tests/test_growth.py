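import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dripfert.growth import (
    CropGrowthParams,
    GrowthState,
    advance_roots,
    align_cycle_to_plantlet,
    beta1_from_yield,
    flowering_stress,
    gdd,
    logistic_inverse,
    logistic_sdw,
    maturity_check,
    sdw_check,
    thermal_stress_coeff,
    water_stress_sdw,
)


@pytest.fixture
def params():
    return CropGrowthParams(
        beta1=6.0, beta2=4.0, beta3=-0.005, t_base=10.0, t_m1=35.0, t_m2=45.0,
        k_t1=0.0, k_t2=0.0, k_t3=0.0, k_sdw1=1.0, k_sdw2=0.5,
        plts_ref=1.0, plts_gr=0.1, ts_min=1400.0, ts_max=2300.0, d_sdwstop=3,
    )


class TestThermalTime:
    @pytest.mark.parametrize("tmax,tmin,tbase,expected", [
        (30, 20, 10, 15.0),
        (10, 4, 10, 0.0),       # mean below base: no accumulation
        (10.2, 10.0, 10.0, 0.1),
    ])
    def test_gdd(self, tmax, tmin, tbase, expected):
        assert gdd(tmax, tmin, tbase) == pytest.approx(expected)

    @pytest.mark.parametrize("tmax,expected", [
        (35.0, 1.0),   # at the onset threshold: no stress yet
        (45.0, 0.0),   # at the cut-off: growth arrested
        (40.0, 0.5),   # linear midpoint
        (20.0, 1.0),
        (50.0, 0.0),
    ])
    def test_thermal_stress_coeff(self, tmax, expected):
        assert thermal_stress_coeff(tmax, 35.0, 45.0) == pytest.approx(expected)

    def test_stressed_gdd_never_exceeds_raw(self):
        for tmax in np.linspace(20, 50, 31):
            k = thermal_stress_coeff(tmax, 35.0, 45.0)
            g = gdd(tmax, tmax - 10, 10.0)
            assert g * k <= g


class TestLogistic:
    def test_inflection_is_half_asymptote(self):
        t_inf = -4.0 / -0.005
        assert logistic_sdw(t_inf, 6.0, 4.0, -0.005) == pytest.approx(3.0)

    def test_asymptote(self):
        assert logistic_sdw(1e5, 6.0, 4.0, -0.005) == pytest.approx(6.0, rel=1e-6)

    def test_zero_exponent_case(self):
        assert logistic_sdw(800.0, 6.0, 4.0, -0.005) == pytest.approx(3.0)

    @given(sdw=st.floats(0.01, 5.99))
    @settings(max_examples=50, deadline=None)
    def test_inverse_round_trip(self, sdw):
        tt = logistic_inverse(sdw, 6.0, 4.0, -0.005)
        assert logistic_sdw(tt, 6.0, 4.0, -0.005) == pytest.approx(sdw, rel=1e-9)


class TestBeta1FromYield:
    def test_hand_arithmetic(self):
        assert beta1_from_yield(2000, 6.0, 0.6, 30000) == pytest.approx(6.0)

    def test_identity_factors(self):
        assert beta1_from_yield(1.0, 100.0, 1.0, 1_000_000) == pytest.approx(1.0)

    def test_halving_hi_doubles_beta1(self):
        assert beta1_from_yield(2000, 6.0, 0.3, 30000) == pytest.approx(
            2 * beta1_from_yield(2000, 6.0, 0.6, 30000))


class TestFloweringStress:
    def test_no_penalty_at_threshold(self):
        assert flowering_stress(6.0, 32.0, 32.0, 100.0) == 6.0

    def test_one_degree_over(self):
        assert flowering_stress(6.0, 33.0, 32.0, 100.0) == pytest.approx(5.94)

    def test_hot_days_compound_multiplicatively(self):
        b = flowering_stress(6.0, 34.0, 32.0, 100.0)
        b = flowering_stress(b, 34.0, 32.0, 100.0)
        assert b == pytest.approx(6.0 * 0.98**2)

    def test_catastrophic_heat_floors_at_zero(self):
        with pytest.warns(UserWarning, match="crop failure"):
            assert flowering_stress(6.0, 200.0, 32.0, 100.0) == 0.0


class TestWaterStress:
    def test_no_stress_when_raw_covers_demand(self):
        assert water_stress_sdw(0.1, 30.0, 40.0, 100.0, 35.0, 0.8) == 0.1

    def test_zero_response_factor(self):
        assert water_stress_sdw(0.1, 80.0, 10.0, 100.0, 35.0, 0.0) == 0.1

    def test_monotone_reading_full_depletion_is_worst(self):
        # loss grows with the deficit beyond RAW; at total depletion the
        # reduction equals ky_b
        partial = water_stress_sdw(0.1, 50.0, 20.0, 100.0, 35.0, 0.8)
        total = water_stress_sdw(0.1, 500.0, 0.0, 100.0, 35.0, 0.8)
        assert total < partial < 0.1
        assert total == pytest.approx(0.1 * (1 - 0.8))

    def test_literal_form_available_behind_flag(self):
        lit = water_stress_sdw(0.1, 500.0, 0.0, 100.0, 35.0, 0.8, literal_eq7=True)
        assert lit == pytest.approx(0.1)  # the printed form's zero-loss corner


class TestSdwCheck:
    def test_identity_when_observation_matches(self, params):
        st_ = GrowthState(sdw=2.0, beta1_current=6.0, t_m2_current=45.0)
        t_m2, b1 = sdw_check(st_, 2.0, params)
        assert b1 == pytest.approx(6.0)

    def test_degenerate_quadratic_gives_constant_tm2(self, params):
        p = CropGrowthParams(**{**params.__dict__, "k_t1": 0.0, "k_t2": 0.0,
                                "k_t3": 43.0})
        st_ = GrowthState(sdw=2.0, beta1_current=6.0, t_m2_current=45.0)
        t_m2, _ = sdw_check(st_, 1.4, p)
        assert t_m2 == 43.0

    def test_rho_power_rescale(self, params):
        st_ = GrowthState(sdw=1.0, beta1_current=6.0, t_m2_current=45.0)
        _, b1 = sdw_check(st_, 1.2, params)  # k_sdw1=1, k_sdw2=0.5
        assert b1 == pytest.approx(6.0 * math.sqrt(1.2))

    def test_nonpositive_observation_rejected(self, params):
        st_ = GrowthState(sdw=1.0, beta1_current=6.0, t_m2_current=45.0)
        with pytest.raises(ValueError):
            sdw_check(st_, 0.0, params)


class TestPlantletAlignment:
    def test_reference_plantlet_no_offset(self, params):
        assert align_cycle_to_plantlet(1.0, params) == (0, 0.0)

    def test_light_plantlet_linear_lag(self, params):
        lag, tt0 = align_cycle_to_plantlet(0.5, params)  # deficit 0.5 g at 0.1 g/d
        assert lag == 5
        assert tt0 == 0.0

    def test_heavy_plantlet_shifts_forward(self, params):
        # 30 g plantlets at 30000/ha put the stand above the curve's origin
        lag, tt0 = align_cycle_to_plantlet(30.0, params)
        assert lag == 0
        assert tt0 > 0.0

    def test_implausible_mass_rejected(self, params):
        with pytest.raises(ValueError):
            align_cycle_to_plantlet(150.0, params)


class TestRoots:
    def test_initial_and_final_dimensions(self, params):
        r0 = advance_roots(0, params)
        assert (r0.r, r0.depth) == (params.root_r_ini, params.root_h_ini)
        rmax = advance_roots(params.root_d_max, params)
        assert (rmax.r, rmax.depth) == (params.root_r_max, params.root_h_max)
        assert advance_roots(params.root_d_max + 30, params).erv == rmax.erv

    def test_erv_hand_arithmetic(self):
        p = CropGrowthParams(
            beta1=6, beta2=4, beta3=-0.005, t_base=10, t_m1=35, t_m2=45,
            root_r_max=30, root_h_max=40, root_d_max=10,
        )
        geom = advance_roots(10, p)
        assert geom.erv == pytest.approx(math.pi * 30 * 30 * (2 * 40 / 3))
        assert geom.erv == pytest.approx(75398.22, abs=0.5)

    def test_twin_row_sandy_reduces_r1_and_shifts_center(self, params):
        g = advance_roots(20, params, twin_row_sandy=True)
        ref = advance_roots(20, params, twin_row_sandy=False)
        assert g.r1 < ref.r1
        assert g.center_offset == pytest.approx(ref.r1 - g.r1)


class TestMaturity:
    def test_vegetative_crop_matures_at_ts_min(self, params):
        p = CropGrowthParams(**{**params.__dict__, "hrvst_type": "vegetative"})
        st_ = GrowthState(thermal_time=1400.0)
        assert maturity_check(st_, p, 12.0, 0.01)

    def test_fruit_plateau_needs_minimum_thermal_sum(self, params):
        st_ = GrowthState(thermal_time=800.0)
        for _ in range(10):
            assert not maturity_check(st_, params, 12.0, 0.001)

    def test_fruit_crop_matures_after_consecutive_plateau_days(self, params):
        st_ = GrowthState(thermal_time=1500.0)
        assert not maturity_check(st_, params, 12.0, 0.001)
        assert not maturity_check(st_, params, 12.0, 0.001)
        assert maturity_check(st_, params, 12.0, 0.001)  # d_sdwstop = 3

    def test_plateau_counter_resets_on_growth_day(self, params):
        st_ = GrowthState(thermal_time=1500.0)
        maturity_check(st_, params, 12.0, 0.001)
        maturity_check(st_, params, 12.0, 0.01)  # growth resumed
        assert st_.days_low_growth == 0

    def test_ts_max_forces_maturity(self, params):
        st_ = GrowthState(thermal_time=2300.0)
        assert maturity_check(st_, params, 12.0, 0.05)
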