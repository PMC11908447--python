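"""Decomposition matrices and apparent-migration accounting."""

import numpy as np
import pandas as pd
import pytest

from dasypop import (
    DecompositionSeries,
    RegionConfig,
    aggregate_migration,
    county_apparent_migration,
    decadal_zone_changes,
    decompose_change,
    delineate_low_land,
    generate_history,
    relative_elevation_grid,
    zone_population_series,
)
from dasypop.synthetic import MigrationConfig


def _series_from_matrix(cells: dict[tuple[int, int], float], county="c") -> DecompositionSeries:
    rows = [
        {"census_year": cy, "sea_level_year": sly, "county": county, "subgroup": g,
         "population": v if g == "total" else 0.0}
        for (cy, sly), v in cells.items()
        for g in ("total", "black", "hispanic")
    ]
    return DecompositionSeries(pd.DataFrame(rows))


def test_decomposition_of_worked_example():
    """A 150k census decline in the terminal zone plus a 100k sea-level
    gain nets to a 50k actual decline."""
    series = _series_from_matrix(
        {(2000, 2000): 1_050_000, (2000, 2010): 1_150_000,
         (2010, 2000): 900_000, (2010, 2010): 1_000_000}
    )
    comp = decompose_change(series, 2000, 2010)
    assert comp["delta_census"] == -150_000
    assert comp["delta_sea_level"] == +100_000
    assert comp["actual"] == -50_000
    assert comp["cross_term"] == 0


def test_decomposition_degenerate_and_order():
    series = _series_from_matrix({(2000, 2000): 5.0})
    comp = decompose_change(series, 2000, 2000)
    assert all(v == 0 for v in comp.values())
    with pytest.raises(ValueError):
        decompose_change(series, 2010, 2000)


def test_zero_rise_rate_makes_columns_identical():
    b = generate_history(RegionConfig(seed=2, rise_rate_mm_per_yr=0.0,
                                      census_years=(1990, 2000)))
    zones = {}
    for y in (1990, 2000):
        rel = relative_elevation_grid(b.elevation, b.tidal, b.rise_rate, y)
        zones[y] = delineate_low_land(rel, 1.0, b.water)
    series = zone_population_series(b.blocks, zones, b.buildings, "building",
                                    b.water_polygon())
    m = series.matrix("total")
    np.testing.assert_allclose(m[1990], m[2000])
    comp = decompose_change(series, 1990, 2000)
    assert comp["delta_sea_level"] == pytest.approx(0.0)


def test_frozen_population_makes_rows_identical():
    cfg = RegionConfig(seed=2, split_prob=0.0,
                       migration=MigrationConfig(base_rate=0.0, low_rate=0.0),
                       census_years=(1990, 2000))
    b = generate_history(cfg)
    zones = {}
    for y in (1990, 2000):
        rel = relative_elevation_grid(b.elevation, b.tidal, b.rise_rate, y)
        zones[y] = delineate_low_land(rel, 1.0, b.water)
    series = zone_population_series(b.blocks, zones, b.buildings, "building",
                                    b.water_polygon())
    m = series.matrix("total")
    np.testing.assert_allclose(m.loc[1990], m.loc[2000])
    assert decompose_change(series, 1990, 2000)["delta_census"] == pytest.approx(0.0)


def test_matrix_cells_match_ground_truth_when_blocks_unsplit():
    """With a threshold high enough that every block lies entirely in
    the zone, estimates are exact, so each cell must equal the direct
    person count for that census year."""
    b = generate_history(RegionConfig(seed=4, census_years=(1990, 2000)))
    zones = {}
    for y in (1990, 2000):
        rel = relative_elevation_grid(b.elevation, b.tidal, b.rise_rate, y)
        zones[y] = delineate_low_land(rel, 50.0, b.water)  # everything dry is below 50 m
    series = zone_population_series(b.blocks, zones, b.buildings, "building",
                                    b.water_polygon())
    for cy in (1990, 2000):
        for sly in (1990, 2000):
            truth = b.true_zone_count(cy, zones[sly].contains_points)
            assert series.cell(cy, sly) == pytest.approx(truth)


def test_mismatched_zone_thresholds_rejected(region):
    rel = relative_elevation_grid(region.elevation, region.tidal, region.rise_rate, 2020)
    z1 = delineate_low_land(rel, 1.0, region.water)
    z2 = delineate_low_land(rel, 2.0, region.water)
    with pytest.raises(ValueError, match="threshold"):
        zone_population_series(region.blocks, {1990: z1, 2020: z2}, region.buildings)


# -- emigration accounting -------------------------------------------

# Decadal changes as printed for six internally consistent counties,
# with their printed 30-year totals.
COUNTY_DECADALS = {
    ("Orleans", "LA"): ([-11_361, -130_806, 41_188], -100_979),
    ("St. Bernard", "LA"): ([319, -25_638, 6_963], -18_356),
    ("Jefferson", "LA"): ([5_644, -21_027, 6_929], -8_454),
    ("Cameron", "LA"): ([-61, -2_255, -340], -2_656),
    ("Plaquemines", "LA"): ([1_076, -3_690, 574], -2_040),
    ("Jefferson", "TX"): ([-2_225, -3_182, -986], -6_393),
}


def test_thirty_year_totals_from_printed_decadal_changes():
    rows = []
    for (county, state), (decades, _) in COUNTY_DECADALS.items():
        for period, change in zip(("1990s", "2000s", "2010s"), decades):
            rows.append({"county": f"{county} {state}", "period": period, "change": change})
    table = aggregate_migration(pd.DataFrame(rows)).table.set_index("county")
    for (county, state), (_, total) in COUNTY_DECADALS.items():
        assert table.loc[f"{county} {state}", "change_full"] == total
    # national apparent emigration sums the negative 30-year changes
    expected = sum(t for _, t in COUNTY_DECADALS.values() if t < 0)
    got = aggregate_migration(
        pd.DataFrame(rows)
    ).national["total"]
    assert got == expected


def test_no_negative_changes_means_zero_emigration():
    decadal = pd.DataFrame(
        {"county": ["a", "a", "b", "b"], "period": ["1990s", "2000s"] * 2,
         "change": [5.0, 3.0, 0.0, 2.0]}
    )
    assert aggregate_migration(decadal).national["total"] == 0.0


def test_path_consistency_and_ground_truth_recount(region, water_poly):
    """Decadal changes telescope to the full-period change, and the
    accounting applied to exact person counts reproduces the logged
    removals that occurred inside the zone."""
    rel = relative_elevation_grid(region.elevation, region.tidal, region.rise_rate, 2020)
    zone = delineate_low_land(rel, 1.0, region.water)
    # ground-truth decadal changes from person points
    years = region.census_years
    rows = []
    for county in sorted(region.blocks[years[0]]["county"].unique()):
        for a, b in zip(years, years[1:]):
            def in_zone_count(year):
                ppl = region.persons[year]
                sel = ppl["block_id"].str.startswith(f"c{county[-1]}")
                inz = zone.contains_points(ppl.loc[sel, "x"].to_numpy(),
                                           ppl.loc[sel, "y"].to_numpy())
                return int(inz.sum())
            rows.append({"county": county, "period": f"{a}s",
                         "change": in_zone_count(b) - in_zone_count(a)})
    decadal = pd.DataFrame(rows)
    table = aggregate_migration(decadal).table.set_index("county")
    # telescoping: full change equals the sum of decadal changes (exact)
    for county in table.index:
        per = decadal[decadal["county"] == county]["change"].sum()
        assert table.loc[county, "change_full"] == per
    # persons never move, so a county's zone loss equals its logged
    # removals that were inside the zone
    removed_in_zone = {c: 0 for c in table.index}
    for year, rec in region.metadata["removed"].items():
        ppl = rec["persons"]
        inz = zone.contains_points(ppl["x"].to_numpy(), ppl["y"].to_numpy())
        for bid in ppl.loc[inz, "block_id"]:
            county = "county" + bid.split("_")[0][1:]
            removed_in_zone[county] += 1
    for county in table.index:
        assert table.loc[county, "change_full"] == -removed_in_zone[county]


def test_flagging_against_county_base_population(region, water_poly):
    rel = relative_elevation_grid(region.elevation, region.tidal, region.rise_rate, 2020)
    zones = {}
    for y in region.census_years:
        rel_y = relative_elevation_grid(region.elevation, region.tidal, region.rise_rate, y)
        zones[y] = delineate_low_land(rel_y, 1.0, region.water)
    series = zone_population_series(region.blocks, zones, region.buildings,
                                    "building", water_poly)
    county_pops = (
        region.blocks[1990].groupby("county")[["pop_total", "pop_black", "pop_hispanic"]]
        .sum().reset_index()
    )
    emig = county_apparent_migration(series, county_pops, threshold_pct=1.0)
    t = emig.table.set_index("county")
    for county in t.index:
        base = county_pops.set_index("county").loc[county, "pop_total"]
        assert t.loc[county, "flagged"] == (abs(t.loc[county, "change_full"]) / base > 0.01)
    # emigration totals are non-positive by construction
    assert emig.national["total"] <= 0
    # decadal changes computed against a single terminal-year zone
    dec = decadal_zone_changes(series)
    assert set(dec["period"]) == {f"{y}s" for y in region.census_years[:-1]}
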