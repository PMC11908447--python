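import logging

import pytest

from dasypop import (
    RegionConfig,
    block_zone_fractions,
    delineate_low_land,
    generate_history,
    relative_elevation_grid,
)

logging.getLogger("dasypop").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def region():
    """Default synthetic region: 2 counties x 100 blocks, 5000 persons,
    four censuses 1990-2020, buildings avoiding low ground."""
    return generate_history(RegionConfig(seed=7))


@pytest.fixture(scope="session")
def water_poly(region):
    return region.water_polygon()


@pytest.fixture(scope="session")
def zone_1m(region):
    """Dry land below 1 m of 2020 sea level."""
    rel = relative_elevation_grid(region.elevation, region.tidal, region.rise_rate, 2020)
    return delineate_low_land(rel, 1.0, region.water)


@pytest.fixture(scope="session")
def fractions_2020(region, zone_1m, water_poly):
    return block_zone_fractions(region.blocks[2020], zone_1m, region.buildings, water_poly)
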