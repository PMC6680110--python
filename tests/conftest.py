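import pytest

from nutricost import (
    CurrencyContext,
    RegionDemographics,
    packaged_scenario,
)
from nutricost.synthetic import fixture_targets


@pytest.fixture(scope="session")
def ctx():
    return CurrencyContext()


@pytest.fixture(scope="session")
def sun_scenario():
    return packaged_scenario("sun")


@pytest.fixture(scope="session")
def india_plus_scenario():
    return packaged_scenario("india_plus")


@pytest.fixture(scope="session")
def sun_targets(sun_scenario):
    return fixture_targets(sun_scenario)


@pytest.fixture(scope="session")
def india_plus_targets(india_plus_scenario):
    return fixture_targets(india_plus_scenario)


def make_region(
    region_id="toy",
    total=1_000_000.0,
    cbr=20.0,
    growth=0.01,
    prev_whz_m3=0.05,
    prev_whz_m2=0.15,
    prev_waz_m3=0.08,
    frac_govt=0.03,
    endemic=False,
    base_year=2011,
):
    """A single-band toy region covering [0, 100) years, split evenly by sex."""
    bands = {(0.0, 100.0, "m"): total / 2, (0.0, 100.0, "f"): total / 2}
    return RegionDemographics(
        region_id=region_id,
        base_year=base_year,
        population_by_band=bands,
        crude_birth_rate=cbr,
        growth_rate=growth,
        prev_whz_lt_m3=prev_whz_m3,
        prev_whz_lt_m2=prev_whz_m2,
        prev_waz_lt_m3=prev_waz_m3,
        frac_women_govt=frac_govt,
        malaria_endemic=endemic,
    )


@pytest.fixture
def toy_region():
    return make_region()
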