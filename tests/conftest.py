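import pytest

from dripfert.engine import PlantLayout, SectorConfig
from dripfert.et0 import ET0Params
from dripfert.growth import CropGrowthParams
from dripfert.soil import SoilChemistry, SoilTexture
from dripfert.water import IrrigationHardware
from dripfert.weather import multiannual_mean, synth_weather

CAL_WINDOW = (161, 263)  # 10 Jun - 20 Sep (non-leap)


@pytest.fixture(scope="session")
def six_years():
    """Six years of synthetic Mediterranean weather (fixed seed)."""
    return synth_weather(years=6, seed=1).split_years()


@pytest.fixture(scope="session")
def mean_series():
    """Multiannual-mean series for pre-season simulations."""
    return multiannual_mean(synth_weather(years=5, seed=9))


@pytest.fixture
def et0_params():
    return ET0Params()


@pytest.fixture
def tomato_config():
    """Processing-tomato-like sector on a clay-loam soil (the defaults)."""
    return SectorConfig()


def make_no_stress_config(**overrides):
    """A leafy-vegetable sector sized so water and N never limit growth."""
    kwargs = dict(
        crop=CropGrowthParams(
            beta1=4.0, beta2=5.0, beta3=-0.005, t_base=10.0, t_m1=40.0, t_m2=48.0,
            ky_b=0.8, ts_min=2000.0, ts_max=2600.0, hrvst_type="vegetative",
        ),
        hardware=IrrigationHardware(lines_dist=100.0, emit_dist=30.0, e_disch=4.0),
        layout=PlantLayout(in_row=30.0, bet_rows=100.0),
        raw_pct=0.50,
        pre_n=300.0,
    )
    kwargs.update(overrides)
    return SectorConfig(**kwargs)


def make_poor_soil_config(**overrides):
    """Low-fertility soil so fertigation doses are actually demanded."""
    kwargs = dict(
        chemistry=SoilChemistry(som=10.0, n_org=0.5, no3_n=3.0, nh4_n=1.0, caco3=80.0),
        n_min_res_1=25.0, n_min_res_2=40.0, n_min_res_3=15.0,
    )
    kwargs.update(overrides)
    return SectorConfig(**kwargs)


@pytest.fixture
def clay_loam_texture():
    return SoilTexture(sand=40, silt=30, clay=30, organic_matter=2.0, bulk_density=1.35)
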