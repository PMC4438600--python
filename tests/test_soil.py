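import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dripfert.soil import (
    CARSEL_PARRISH,
    SoilHydraulics,
    SoilTexture,
    classify_usda,
    default_hydraulics,
    default_ks,
    hydraulic_conductivity,
    pedotransfer,
    pressure_head,
    relative_saturation,
)


class TestTexture:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="100"):
            SoilTexture(sand=50, silt=30, clay=30)

    def test_small_lab_drift_renormalized(self):
        t = SoilTexture(sand=40.2, silt=30.0, clay=30.1)
        assert t.sand + t.silt + t.clay == pytest.approx(100.0)


class TestClassifyUsda:
    @pytest.mark.parametrize(
        "sand,silt,clay,expected",
        [
            (92, 5, 3, "sand"),
            (20, 20, 60, "clay"),
            (33, 33, 34, "clay loam"),
            (82, 10, 8, "loamy sand"),
            (60, 30, 10, "sandy loam"),
            (40, 40, 20, "loam"),
            (20, 65, 15, "silt loam"),
            (8, 87, 5, "silt"),
            (60, 12, 28, "sandy clay loam"),
            (10, 56, 34, "silty clay loam"),
            (50, 8, 42, "sandy clay"),
            (8, 47, 45, "silty clay"),
        ],
    )
    def test_triangle_classes(self, sand, silt, clay, expected):
        assert classify_usda(SoilTexture(sand=sand, silt=silt, clay=clay)) == expected

    def test_every_texture_gets_exactly_one_class(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            clay = rng.uniform(0, 100)
            sand = rng.uniform(0, 100 - clay)
            t = SoilTexture(sand=sand, silt=100 - clay - sand, clay=clay)
            assert classify_usda(t) in CARSEL_PARRISH


class TestPedotransfer:
    def test_saxton_default_row(self):
        # independent evaluation of the Saxton regression at Sa=40, Cl=30
        t = SoilTexture(sand=40, silt=30, clay=30)
        r = pedotransfer(t, 9)
        assert r["theta_wp"] == pytest.approx(0.169525, abs=1e-5)
        assert r["theta_fc"] == pytest.approx(0.296516, abs=1e-5)
        assert r["bulk_density"] == pytest.approx((1 - r["theta_sat"]) * 2.65)

    def test_petersen_zero_clay(self):
        r = pedotransfer(SoilTexture(sand=60, silt=40, clay=0), 5)
        assert r["theta_fc"] == pytest.approx(0.1183)
        assert r["theta_wp"] == pytest.approx(0.0174)

    @given(
        sand=st.floats(1, 95),
        clay=st.floats(1, 60),
    )
    @settings(max_examples=100, deadline=None)
    def test_saxton_ordering_always_holds(self, sand, clay):
        if sand + clay >= 100:
            return
        t = SoilTexture(sand=sand, silt=100 - sand - clay, clay=clay)
        r = pedotransfer(t, 9)
        assert 0 < r["theta_wp"] < r["theta_fc"] < 1

    def test_ordering_over_texture_sweep_all_methods(self):
        """0 < WP < FC < 1 for every method, except the documented
        Manrique (method 3) failure region: heavy clay with high bulk
        density, where the printed regression itself inverts FC and WP."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            clay = rng.uniform(0, 60)
            sand = rng.uniform(0, 100 - clay)
            t = SoilTexture(
                sand=sand, silt=100 - clay - sand, clay=clay,
                organic_matter=rng.uniform(0.5, 4.0),
                bulk_density=rng.uniform(1.1, 1.7),
            )
            for method in range(1, 10):
                r = pedotransfer(t, method)
                ok = 0 < r["theta_wp"] < r["theta_fc"] < 1
                if method == 3 and clay > 50 and t.bulk_density > 1.6:
                    continue  # known defect of the printed regression
                assert ok, (method, sand, clay, t.bulk_density, r)

    def test_missing_required_field(self):
        with pytest.raises(ValueError, match="bulk_density"):
            pedotransfer(SoilTexture(sand=40, silt=30, clay=30), 3)

    def test_method_out_of_range(self):
        with pytest.raises(ValueError):
            pedotransfer(SoilTexture(sand=40, silt=30, clay=30), 10)


class TestDefaultKs:
    def test_published_class_means(self):
        assert default_ks("sand") == pytest.approx(712.8)
        assert default_ks("clay") == pytest.approx(4.8)

    def test_sand_faster_than_clay(self):
        assert default_ks("sand") > default_ks("clay")

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            default_ks("gravel")


@pytest.fixture
def hyd():
    return SoilHydraulics(
        theta_fc=0.30, theta_wp=0.12, theta_sat=0.45, theta_res=0.05,
        ks=25.0, vg_alpha=0.036, vg_n=1.56,
    )


class TestRetentionConductivity:
    def test_saturation_limits(self, hyd):
        assert relative_saturation(hyd.theta_sat, hyd) == 1.0
        assert relative_saturation(hyd.theta_res, hyd) == 0.0
        assert pressure_head(1.0, hyd) == 0.0

    def test_hand_value_alpha_001_n2(self):
        # S = [1/(1+(alpha*h)^n)]^m with alpha=0.01, n=2, h=100 -> (1/2)^0.5
        h = SoilHydraulics(
            theta_fc=0.30, theta_wp=0.12, theta_sat=0.45, theta_res=0.05,
            ks=25.0, vg_alpha=0.01, vg_n=2.0,
        )
        s = 0.5 ** (1 - 1 / 2.0)
        assert pressure_head(s, h) == pytest.approx(100.0, rel=1e-9)

    @given(s=st.floats(1e-3, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_saturation_head_mutual_inverse(self, s):
        hyd = SoilHydraulics(
            theta_fc=0.30, theta_wp=0.12, theta_sat=0.45, theta_res=0.05,
            ks=25.0, vg_alpha=0.036, vg_n=1.56,
        )
        h = pressure_head(s, hyd)
        theta = hyd.theta_res + s * (hyd.theta_sat - hyd.theta_res)
        s_back = (1.0 / (1.0 + abs(hyd.vg_alpha * h) ** hyd.vg_n)) ** hyd.vg_m
        assert s_back == pytest.approx(s, rel=1e-9)
        assert relative_saturation(theta, hyd) == pytest.approx(s, rel=1e-9)

    def test_conductivity_limits(self, hyd):
        assert hydraulic_conductivity(hyd.theta_sat, hyd) == pytest.approx(hyd.ks)
        assert hydraulic_conductivity(hyd.theta_res, hyd) == 0.0

    def test_conductivity_hand_value_s_half(self):
        # working form at S=0.5, m=0.5: K = Ks*0.5*(1-(1-0.25))^2 = 0.03125*Ks
        hyd = SoilHydraulics(
            theta_fc=0.30, theta_wp=0.12, theta_sat=0.45, theta_res=0.05,
            ks=100.0, vg_alpha=0.036, vg_n=2.0,
        )
        theta = hyd.theta_res + 0.5 * (hyd.theta_sat - hyd.theta_res)
        assert hydraulic_conductivity(theta, hyd) == pytest.approx(3.125)

    def test_conductivity_monotone_in_theta(self, hyd):
        thetas = np.linspace(hyd.theta_res, hyd.theta_sat, 50)
        ks = [hydraulic_conductivity(t, hyd) for t in thetas]
        assert all(b >= a - 1e-12 for a, b in zip(ks, ks[1:]))

    def test_standard_mualem_differs(self, hyd):
        theta = 0.3
        assert hydraulic_conductivity(theta, hyd, standard_mualem=True) != \
            pytest.approx(hydraulic_conductivity(theta, hyd))


class TestDefaultHydraulics:
    def test_full_assembly_from_texture(self, clay_loam_texture):
        h = default_hydraulics(clay_loam_texture)
        assert h.usda_class == "clay loam"
        assert h.ks == pytest.approx(6.24)
        assert 0 < h.theta_res < h.theta_wp < h.theta_fc < h.theta_sat <= 1
        assert h.vg_n > 1

    def test_measured_values_override(self, clay_loam_texture):
        h = default_hydraulics(clay_loam_texture, theta_fc=0.31, ks=12.0)
        assert h.theta_fc == 0.31
        assert h.ks == 12.0
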