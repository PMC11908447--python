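"""Disproportionality ratios: identities, toys, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from dasypop import (
    RegionConfig,
    county_weighted_disproportionality,
    delineate_low_land,
    emigration_disparity,
    generate_history,
    nationwide_disproportionality,
    overlay_disparity,
    relative_elevation_grid,
    residence_disparity,
)
from dasypop.hazard import HazardZone
from dasypop.synthetic import MigrationConfig


def test_nationwide_ratio_from_printed_shares():
    """A 19.5% zone share against a 12% national share is a ratio of
    1.625, printed as 1.63."""
    ratio = nationwide_disproportionality(
        {"total": 1000.0, "black": 195.0}, {"total": 1000.0, "black": 120.0}
    )
    assert ratio == pytest.approx(0.195 / 0.12)
    assert round(ratio, 2) == 1.63 or abs(ratio - 1.63) <= 0.005


def test_nationwide_ratio_trivial_and_toy():
    assert nationwide_disproportionality(
        {"total": 50, "black": 10}, {"total": 500, "black": 100}
    ) == pytest.approx(1.0)
    # two-county toy by direct arithmetic: zone 30 Black of 120;
    # reference 100 Black of 1000
    ratio = nationwide_disproportionality(
        {"total": 120, "black": 30}, {"total": 1000, "black": 100}
    )
    assert ratio == pytest.approx((30 / 120) / (100 / 1000))


def test_nationwide_zero_reference_subgroup_is_nan():
    assert np.isnan(
        nationwide_disproportionality({"total": 10, "black": 1}, {"total": 10, "black": 0})
    )


def _county_table(rows):
    return pd.DataFrame(
        rows, columns=["zone_subgroup", "zone_total", "county_subgroup", "county_total"]
    )


def test_county_weighted_unity_under_proportionality():
    # in every county the subgroup's zone share equals its county share
    t = _county_table([(20, 100, 200, 1000), (5, 50, 300, 3000), (0, 0, 100, 500)])
    assert county_weighted_disproportionality(t) == pytest.approx(1.0)


def test_county_weighted_two_county_toy():
    # (zone_sub, zone_tot, county share) = (10, 100, 0.2), (30, 100, 0.1)
    # expected = 100*0.2 + 100*0.1 = 30; observed = 40 -> 4/3
    t = _county_table([(10, 100, 200, 1000), (30, 100, 100, 1000)])
    assert county_weighted_disproportionality(t) == pytest.approx(40.0 / 30.0)


def test_scale_invariance_of_both_ratios():
    t = _county_table([(10, 100, 200, 1000), (30, 100, 100, 1000)])
    for c in (3.0, 0.5):
        scaled = t * c
        assert county_weighted_disproportionality(scaled) == pytest.approx(
            county_weighted_disproportionality(t)
        )
        m, ms = residence_disparity(t), residence_disparity(scaled)
        assert ms.nationwide_ratio == pytest.approx(m.nationwide_ratio)


def test_ratios_coincide_with_identical_county_shares():
    # both counties 15% Black: nationwide and county-weighted agree
    t = _county_table([(12, 100, 150, 1000), (30, 120, 300, 2000)])
    m = residence_disparity(t)
    assert m.county_weighted_ratio == pytest.approx(m.nationwide_ratio)


def test_county_weighted_is_inverse_weighted_average():
    """The county-weighted ratio equals the expected-counts quotient and
    can be rewritten as an inverse weighted average of county ratios."""
    t = _county_table([(10, 100, 200, 1000), (30, 100, 100, 1000), (8, 40, 50, 400)])
    cw = county_weighted_disproportionality(t)
    r_c = (t["zone_subgroup"] / t["zone_total"]) / (t["county_subgroup"] / t["county_total"])
    obs = t["zone_subgroup"]
    assert cw == pytest.approx(obs.sum() / (obs / r_c).sum())


def test_emigration_shares_from_printed_totals():
    m = emigration_disparity({"total": 169, "black": 98}, {"total": 1000, "black": 120})
    assert round(m.share_zone, 2) == 0.58
    m = emigration_disparity({"total": 226, "black": 119}, {"total": 1000, "black": 120})
    assert round(m.share_zone, 2) == 0.53


def test_emigration_proportional_gives_unit_county_ratio():
    per_county = pd.DataFrame(
        {
            "emig_subgroup": [4.0, 9.0],
            "emig_total": [40.0, 30.0],
            "county_subgroup": [100.0, 300.0],
            "county_total": [1000.0, 1000.0],
        }
    )
    m = emigration_disparity(
        {"total": 70, "black": 13}, {"total": 2000, "black": 400}, per_county=per_county
    )
    assert m.county_weighted_ratio == pytest.approx(1.0)


def test_zero_emigration_flagged_nan():
    m = emigration_disparity({"total": 0, "black": 0}, {"total": 100, "black": 10})
    assert np.isnan(m.share_zone)


def test_biased_emigration_recovered_from_ground_truth():
    """With Black low-elevation emigration boosted by a known factor,
    the disparity computed from the generator's logged removals must
    sit near the generative bias, within binomial Monte-Carlo error."""
    mult = 3.0
    cfg = RegionConfig(
        seed=9,
        census_years=(1990, 2000),
        migration=MigrationConfig(base_rate=0.0, low_rate=0.08,
                                  black_low_multiplier=mult),
    )
    b = generate_history(cfg)
    removed = b.metadata["removed"][2000]["persons"]
    base = b.persons[1990]
    # oracle: expected removals from the known per-person probabilities
    elev = b.elevation.values_at(base["x"].to_numpy(), base["y"].to_numpy())
    low = elev < 1.0
    p = 0.08 * low * np.where(base["black"].to_numpy() == 1, mult, 1.0)
    exp_total, exp_black = p.sum(), p[base["black"].to_numpy() == 1].sum()
    m = emigration_disparity(
        {"total": len(removed), "black": int(removed["black"].sum())},
        {"total": len(base), "black": int(base["black"].sum())},
    )
    expected_ratio = (exp_black / exp_total) / (base["black"].mean())
    se = 3 * np.sqrt(1.0 / max(exp_black, 1))  # generous binomial-scale error
    assert m.nationwide_ratio == pytest.approx(expected_ratio, abs=max(3 * se, 0.3))
    assert m.nationwide_ratio > 1.5  # the bias is clearly visible


# -- categorical overlays --------------------------------------------


def _overlay_scene():
    blocks = pd.DataFrame(
        {
            "block_id": ["b1", "b2"],
            "county": ["c", "c"],
            "geometry": [box(0, 0, 100, 100), box(100, 0, 200, 100)],
            "pop_total": [100, 100],
            "pop_black": [10, 10],
            "pop_hispanic": [5, 5],
            "housing_units": [40, 40],
        }
    )
    # b1 buildings all low (x < 50), b2 all high
    buildings = pd.DataFrame(
        {
            "x": [10.0, 20, 30, 40, 110, 120, 130, 140],
            "y": [50.0] * 8,
        }
    )
    zone = HazardZone(geometry=box(0, 0, 50, 100), zone_type="elevation", threshold_z_m=1.0)
    return blocks, buildings, zone


def test_overlay_single_category_has_unit_ratio():
    blocks, buildings, zone = _overlay_scene()
    overlay = pd.DataFrame({"geometry": [box(0, 0, 200, 100)], "category": ["all"]})
    out = overlay_disparity(zone, overlay, blocks, buildings).set_index("category")
    assert out.loc["all", "ratio_vs_overall"] == pytest.approx(1.0)


def test_overlay_category_covering_only_zone_land():
    blocks, buildings, zone = _overlay_scene()
    overlay = pd.DataFrame(
        {"geometry": [box(0, 0, 50, 100), box(50, 0, 200, 100)],
         "category": ["low", "high"]}
    )
    out = overlay_disparity(zone, overlay, blocks, buildings).set_index("category")
    overall = out.loc["__overall__", "zone_share"]
    assert out.loc["low", "zone_share"] == pytest.approx(1.0)
    assert out.loc["low", "ratio_vs_overall"] == pytest.approx(1.0 / overall)
    assert out.loc["high", "population_in_zone"] == pytest.approx(0.0)


def test_overlapping_overlay_rejected():
    blocks, buildings, zone = _overlay_scene()
    overlay = pd.DataFrame(
        {"geometry": [box(0, 0, 120, 100), box(100, 0, 200, 100)],
         "category": ["a", "b"]}
    )
    with pytest.raises(ValueError, match="overlap"):
        overlay_disparity(zone, overlay, blocks, buildings)


def test_overlay_shares_match_ground_truth_persons():
    """On a synthetic region, building-weighted overlay shares must
    track the true person counts for a category that is exactly the
    low-lying land."""
    b = generate_history(RegionConfig(seed=8, census_years=(1990, 2000)))
    rel = relative_elevation_grid(b.elevation, b.tidal, b.rise_rate, 2000)
    zone = delineate_low_land(rel, 1.0, b.water)
    bounds = b.elevation.bounds
    overlay = pd.DataFrame(
        {"geometry": [zone.geometry,
                      box(*bounds).difference(zone.geometry)],
         "category": ["low", "rest"]}
    )
    out = overlay_disparity(zone, overlay, b.blocks[2000], b.buildings,
                            water_poly=b.water_polygon()).set_index("category")
    ppl = b.persons[2000]
    inz = zone.contains_points(ppl["x"].to_numpy(), ppl["y"].to_numpy())
    truth_low = int(inz.sum())
    # the "low" category is the zone itself: its in-zone population is its population
    assert out.loc["low", "zone_share"] == pytest.approx(1.0, abs=1e-6)
    assert out.loc["low", "population_in_zone"] == pytest.approx(truth_low, rel=0.15)
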