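"""Disproportionality (environmental-justice) ratios for hazard zones.

Two scales of the same question — "does a subgroup disproportionately
live in (or emigrate from) the hazard zone?":

* **nationwide ratio** — the subgroup's share of the zone population
  divided by its share of the reference population.  It mixes two
  effects: subgroups concentrating in the most vulnerable *counties*,
  and concentrating on the vulnerable land *within* counties.
* **county-weighted ratio** — the observed national subgroup total in
  the zone divided by what that total would be if, within every county,
  subgroup presence in the zone were proportional to the subgroup's
  county share.  This filters out between-county composition and leaves
  only the within-county effect; algebraically it is an inverse
  weighted average of county-specific ratios.

The same construction applies to emigration totals (with base-year
reference populations) and to any categorical overlay (e.g. historical
lending-risk maps) via the dasymetric machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from .dasymetric import estimate_zone_population
from .hazard import HazardZone
from .region import POP_COLUMN, assign_points_to_blocks

log = logging.getLogger(__name__)


@dataclass
class DisparityMetrics:
    """Shares and ratios for one (zone, subgroup, measure) combination."""

    subgroup: str
    measure: str  # "residents" or "emigration"
    share_zone: float
    share_reference: float
    nationwide_ratio: float
    county_weighted_ratio: float | None = None


def nationwide_disproportionality(
    zone_pop: Mapping[str, float], reference_pop: Mapping[str, float], subgroup: str = "black"
) -> float:
    """(subgroup share of zone population) / (subgroup share of reference).

    ``zone_pop`` and ``reference_pop`` map subgroup names (including
    "total") to counts.  Returns NaN with a warning when the reference
    subgroup is empty.
    """
    if zone_pop["total"] <= 0 or reference_pop["total"] <= 0:
        raise ValueError("total populations must be positive")
    ref_share = reference_pop[subgroup] / reference_pop["total"]
    if ref_share == 0:
        log.warning("reference %s population is zero; ratio undefined", subgroup)
        return float("nan")
    zone_share = zone_pop[subgroup] / zone_pop["total"]
    return zone_share / ref_share


def county_weighted_disproportionality(per_county: pd.DataFrame) -> float:
    """Observed subgroup zone total / expected total under within-county
    proportionality.

    ``per_county`` has one row per county with columns ``zone_subgroup``,
    ``zone_total``, ``county_subgroup``, ``county_total``.  The expected
    count for a county is its zone total times the subgroup's share of
    the county population; counties with no zone population contribute
    zero to both sums.  Returns NaN with a warning when the expected
    total is zero.
    """
    d = per_county
    valid = d["county_total"] > 0
    if not valid.all():
        log.warning("%d county rows with zero population skipped", int((~valid).sum()))
        d = d[valid]
    observed = float(d["zone_subgroup"].sum())
    expected = float((d["zone_total"] * d["county_subgroup"] / d["county_total"]).sum())
    if expected == 0:
        log.warning("expected subgroup zone total is zero; ratio undefined")
        return float("nan")
    return observed / expected


def emigration_disparity(
    emigration: Mapping[str, float],
    base_pop: Mapping[str, float],
    subgroup: str = "black",
    per_county: pd.DataFrame | None = None,
) -> DisparityMetrics:
    """Disproportionality of emigration from a hazard zone.

    ``emigration`` maps subgroups to apparent-emigration totals (signed
    changes or positive magnitudes; magnitudes are used).  ``base_pop``
    is the base-year reference population.  ``per_county``, if given,
    provides columns ``emig_subgroup``, ``emig_total``,
    ``county_subgroup``, ``county_total`` (emigration as magnitudes) for
    the county-weighted analogue.
    """
    e_tot = abs(emigration["total"])
    e_sub = abs(emigration[subgroup])
    if e_tot == 0:
        log.warning("zero total emigration; shares undefined")
        share = float("nan")
    else:
        share = e_sub / e_tot
    ref_share = base_pop[subgroup] / base_pop["total"]
    nw = share / ref_share if ref_share > 0 else float("nan")
    cw = None
    if per_county is not None:
        cw = county_weighted_disproportionality(
            per_county.rename(
                columns={"emig_subgroup": "zone_subgroup", "emig_total": "zone_total"}
            )
        )
    return DisparityMetrics(
        subgroup=subgroup,
        measure="emigration",
        share_zone=share,
        share_reference=ref_share,
        nationwide_ratio=nw,
        county_weighted_ratio=cw,
    )


def residence_disparity(
    per_county: pd.DataFrame, subgroup: str = "black"
) -> DisparityMetrics:
    """Nationwide and county-weighted residence ratios from county tables.

    ``per_county`` columns: ``zone_subgroup``, ``zone_total``,
    ``county_subgroup``, ``county_total`` (terminal-census populations).
    Counties wholly outside the zone are retained — they still count in
    the reference shares.
    """
    zone_pop = {"total": float(per_county["zone_total"].sum()),
                subgroup: float(per_county["zone_subgroup"].sum())}
    ref_pop = {"total": float(per_county["county_total"].sum()),
               subgroup: float(per_county["county_subgroup"].sum())}
    nw = nationwide_disproportionality(zone_pop, ref_pop, subgroup)
    cw = county_weighted_disproportionality(per_county)
    return DisparityMetrics(
        subgroup=subgroup,
        measure="residents",
        share_zone=zone_pop[subgroup] / zone_pop["total"] if zone_pop["total"] else float("nan"),
        share_reference=ref_pop[subgroup] / ref_pop["total"],
        nationwide_ratio=nw,
        county_weighted_ratio=cw,
    )


def overlay_disparity(
    zone: HazardZone,
    overlay: pd.DataFrame,
    blocks: pd.DataFrame,
    buildings: pd.DataFrame,
    method: str = "building",
    water_poly: shapely.Geometry | None = None,
) -> pd.DataFrame:
    """Zone-share ratios for a categorical polygon overlay.

    ``overlay`` holds non-overlapping category polygons (columns
    ``geometry``, ``category``).  For each category the block
    populations are apportioned into the category (and into category
    intersected with zone) with the chosen dasymetric method, yielding
    the category's population, its population in the zone, the zone
    share, and the ratio of that share to the overall population's zone
    share.  Raises on overlapping categories.
    """
    cats = overlay.groupby("category")["geometry"].agg(lambda g: shapely.union_all(list(g)))
    labels = list(cats.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            inter = cats[a].intersection(cats[b])
            if inter.area > 1e-6:
                raise ValueError(f"overlay categories {a!r} and {b!r} overlap")

    est = estimate_zone_population(blocks, zone, buildings, method=method, water_poly=water_poly)
    total_pop = float(blocks[POP_COLUMN["total"]].sum())
    overall_share = est.total("total") / total_pop if total_pop else float("nan")

    bx = buildings["x"].to_numpy()
    by = buildings["y"].to_numpy()
    in_zone_b = zone.contains_points(bx, by)
    b_block = assign_points_to_blocks(bx, by, blocks)
    blk = blocks.set_index("block_id")
    n_per_block = pd.Series(b_block).value_counts()

    rows = []
    for label in labels:
        geom = cats[label]
        shapely.prepare(geom)
        if method == "building":
            in_cat = shapely.contains_xy(geom, bx, by)
            s = pd.Series(b_block)
            # each building carries an equal share of its block's population
            w = (s.map(blk["pop_total"]) / s.map(n_per_block)).fillna(0.0).to_numpy()
            pop_cat = float(w[in_cat].sum())
            pop_cat_zone = float(w[in_cat & in_zone_b].sum())
        else:
            pop_cat = pop_cat_zone = 0.0
            for _, row in blocks.iterrows():
                g = row["geometry"]
                if water_poly is not None and not water_poly.is_empty:
                    g = g.difference(water_poly)
                if g.area == 0:
                    continue
                a_cat = g.intersection(geom).area
                if a_cat == 0:
                    continue
                a_cat_zone = g.intersection(geom).intersection(zone.geometry).area
                pop_cat += row["pop_total"] * a_cat / g.area
                pop_cat_zone += row["pop_total"] * a_cat_zone / g.area
        share = pop_cat_zone / pop_cat if pop_cat else float("nan")
        rows.append(
            {
                "category": label,
                "population": pop_cat,
                "population_in_zone": pop_cat_zone,
                "zone_share": share,
                "ratio_vs_overall": share / overall_share if overall_share else float("nan"),
            }
        )
    rows.append(
        {
            "category": "__overall__",
            "population": total_pop,
            "population_in_zone": est.total("total"),
            "zone_share": overall_share,
            "ratio_vs_overall": 1.0,
        }
    )
    return pd.DataFrame(rows)
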