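"""Zone-population time series, change decomposition, emigration accounting.

The population "below z meters" can change between censuses for two
reasons: the sea rose (the zone grew), or the people changed (growth,
decline, migration).  Crossing every census year with every sea-level
year gives a matrix of zone totals whose diagonal is the actually
observed series; holding the zone fixed isolates the demographic
component and holding the census fixed isolates the sea-level
component.

Apparent emigration is the decline of a county's zone population over a
period, computed against a single zone definition (terminal-year sea
level) so that sea-level growth is not misread as immigration.  It is
"apparent" because deaths in excess of births are indistinguishable
from moves in census counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import shapely

from .dasymetric import block_zone_fractions, estimate_zone_population
from .hazard import HazardZone
from .region import SUBGROUPS


@dataclass
class DecompositionSeries:
    """Zone totals indexed by (census year, sea-level year, county, subgroup)."""

    data: pd.DataFrame  # columns: census_year, sea_level_year, county, subgroup, population
    method: str = "building"
    threshold_z_m: float | None = None

    @property
    def census_years(self) -> list[int]:
        return sorted(self.data["census_year"].unique())

    @property
    def sea_level_years(self) -> list[int]:
        return sorted(self.data["sea_level_year"].unique())

    def cell(self, census_year: int, sea_level_year: int, subgroup: str = "total",
             county: str | None = None) -> float:
        d = self.data
        sel = (
            (d["census_year"] == census_year)
            & (d["sea_level_year"] == sea_level_year)
            & (d["subgroup"] == subgroup)
        )
        if county is not None:
            sel &= d["county"] == county
        if not sel.any():
            raise KeyError(f"no cell for census {census_year}, sea level {sea_level_year}")
        return float(d.loc[sel, "population"].sum())

    def matrix(self, subgroup: str = "total", county: str | None = None) -> pd.DataFrame:
        """Pivot: rows census years, columns sea-level years."""
        d = self.data[self.data["subgroup"] == subgroup]
        if county is not None:
            d = d[d["county"] == county]
        return d.pivot_table(
            index="census_year", columns="sea_level_year", values="population", aggfunc="sum"
        )

    def actual(self, subgroup: str = "total") -> pd.Series:
        """Observed series: census year y in the zone of year y (diagonal)."""
        return pd.Series(
            {y: self.cell(y, y, subgroup) for y in self.census_years if y in self.sea_level_years}
        )

    def census_effect(self, subgroup: str = "total") -> pd.Series:
        """Population per census year with the zone fixed at the terminal year."""
        sl = self.sea_level_years[-1]
        return pd.Series({y: self.cell(y, sl, subgroup) for y in self.census_years})

    def sea_level_effect(self, subgroup: str = "total") -> pd.Series:
        """Terminal census population in the zone of each sea-level year."""
        cy = self.census_years[-1]
        return pd.Series({y: self.cell(cy, y, subgroup) for y in self.sea_level_years})


def zone_population_series(
    censuses: dict[int, pd.DataFrame],
    zones: dict[int, HazardZone],
    buildings: pd.DataFrame,
    method: str = "building",
    water_poly: shapely.Geometry | None = None,
) -> DecompositionSeries:
    """Full (census year x sea-level year) matrix of per-county zone totals.

    ``zones`` maps sea-level year to an elevation hazard zone; all zones
    must share one threshold z.  Raises ``KeyError``-style rejection if
    a census table is missing for a requested year.
    """
    if not censuses:
        raise ValueError("no census tables supplied")
    thresholds = {z.threshold_z_m for z in zones.values()}
    if len(thresholds) > 1:
        raise ValueError(f"zones mix thresholds {sorted(thresholds)}; series requires one z")
    rows = []
    for cy, blocks in sorted(censuses.items()):
        if blocks is None:
            raise ValueError(f"missing census table for year {cy}")
        for sly, zone in sorted(zones.items()):
            fr = block_zone_fractions(blocks, zone, buildings, water_poly)
            est = estimate_zone_population(
                blocks, zone, buildings, method=method, water_poly=water_poly, fractions=fr
            )
            for county, r in est.by_county().iterrows():
                for g in SUBGROUPS:
                    rows.append(
                        {
                            "census_year": cy,
                            "sea_level_year": sly,
                            "county": county,
                            "subgroup": g,
                            "population": float(r[f"est_{g}"]),
                        }
                    )
    return DecompositionSeries(
        data=pd.DataFrame(rows),
        method=method,
        threshold_z_m=next(iter(thresholds)) if thresholds else None,
    )


def decompose_change(series: DecompositionSeries, y0: int, y1: int,
                     subgroup: str = "total") -> dict[str, float]:
    """Split the change from census/sea-level year y0 to y1 into components.

    With C(c, s) the population of census c in the zone of sea-level
    year s:

    * ``delta_census``    = C(y1, y1) - C(y0, y1)  (people changed, zone fixed at y1)
    * ``delta_sea_level`` = C(y1, y1) - C(y1, y0)  (zone changed, census fixed at y1)
    * ``actual``          = C(y1, y1) - C(y0, y0)
    * ``cross_term``      = delta_census + delta_sea_level - actual
      (identical to the residual of the base-anchored convention; it is
      the interaction of population change with zone growth and is
      reported, never silently absorbed).
    """
    if y0 > y1:
        raise ValueError("y0 must not exceed y1")
    c11 = series.cell(y1, y1, subgroup)
    c01 = series.cell(y0, y1, subgroup)
    c10 = series.cell(y1, y0, subgroup)
    c00 = series.cell(y0, y0, subgroup)
    delta_census = c11 - c01
    delta_sea = c11 - c10
    actual = c11 - c00
    return {
        "delta_census": delta_census,
        "delta_sea_level": delta_sea,
        "actual": actual,
        "cross_term": delta_census + delta_sea - actual,
    }


# ---------------------------------------------------------------------
# apparent emigration


@dataclass
class EmigrationTable:
    """Per-county decadal and 30-year apparent-migration accounting.

    ``table`` has one row per county with per-decade changes, the
    full-period change, change as a percent of the county's base-year
    population (per subgroup), and an inclusion flag.  ``national``
    maps each subgroup to the apparent-emigration total: the sum of
    full-period changes over the counties where that subgroup's change
    is negative.
    """

    table: pd.DataFrame
    national: dict[str, float] = field(default_factory=dict)
    threshold_pct: float = 1.0

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def decadal_zone_changes(series: DecompositionSeries, sea_level_year: int | None = None) -> pd.DataFrame:
    """Tidy per-county decadal changes against one fixed zone definition.

    Columns: county, subgroup, period (e.g. "1990s"), change.  The zone
    defaults to the terminal sea-level year.
    """
    sly = sea_level_year if sea_level_year is not None else series.sea_level_years[-1]
    years = series.census_years
    counties = sorted(series.data["county"].unique())
    rows = []
    for county in counties:
        for g in SUBGROUPS:
            for a, b in zip(years, years[1:]):
                rows.append(
                    {
                        "county": county,
                        "subgroup": g,
                        "period": f"{a}s",
                        "change": series.cell(b, sly, g, county) - series.cell(a, sly, g, county),
                    }
                )
    return pd.DataFrame(rows)


def aggregate_migration(
    decadal: pd.DataFrame,
    county_pops: pd.DataFrame | None = None,
    threshold_pct: float = 1.0,
) -> EmigrationTable:
    """Fold decadal zone-population changes into the emigration accounting.

    ``decadal`` is tidy: county, subgroup, period, change (a missing
    subgroup column defaults every row to "total").  The full-period
    change per county is the exact sum of its decadal changes.
    ``county_pops``, if given, holds base-year county populations
    (columns county, pop_total[, pop_black, pop_hispanic]) used for the
    percent columns and the |change| > threshold_pct flag.  The national
    apparent-emigration total per subgroup sums the full-period change
    over counties where that change is negative.
    """
    d = decadal.copy()
    if "subgroup" not in d.columns:
        d["subgroup"] = "total"
    wide = d.pivot_table(index=["county", "subgroup"], columns="period", values="change", aggfunc="sum")
    period_cols = list(wide.columns)
    wide["change_total_period"] = wide[period_cols].sum(axis=1)
    flat = wide.reset_index()

    table = flat[flat["subgroup"] == "total"].drop(columns="subgroup").set_index("county")
    table = table.rename(columns={"change_total_period": "change_full"})
    subgroups = [g for g in flat["subgroup"].unique() if g != "total"]
    for g in subgroups:
        sub = flat[flat["subgroup"] == g].set_index("county")["change_total_period"]
        table[f"change_full_{g}"] = sub

    if county_pops is not None:
        cp = county_pops.set_index("county")
        base = table.index.map(cp["pop_total"])
        table["pct_total"] = 100.0 * table["change_full"] / base
        for g in subgroups:
            col = f"pop_{g}"
            if col in cp.columns:
                denom = pd.Series(table.index.map(cp[col]), index=table.index, dtype=float)
                table[f"pct_{g}"] = 100.0 * table[f"change_full_{g}"] / denom.where(denom > 0)
        table["flagged"] = table["pct_total"].abs() > threshold_pct
    else:
        table["flagged"] = False

    national = {"total": float(table.loc[table["change_full"] < 0, "change_full"].sum())}
    for g in subgroups:
        col = f"change_full_{g}"
        national[g] = float(table.loc[table[col] < 0, col].sum())
    return EmigrationTable(table=table.reset_index(), national=national, threshold_pct=threshold_pct)


def county_apparent_migration(
    series: DecompositionSeries,
    county_pops: pd.DataFrame | None = None,
    threshold_pct: float = 1.0,
    sea_level_year: int | None = None,
) -> EmigrationTable:
    """Apparent migration by county from a zone-population series.

    All changes use a single zone (terminal sea-level year by default);
    percent columns use base-year county populations.
    """
    decadal = decadal_zone_changes(series, sea_level_year)
    return aggregate_migration(decadal, county_pops, threshold_pct)
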