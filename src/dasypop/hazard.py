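"""Year-specific sea-level surfaces and hazard-zone delineation.

"Sea level" here means the local mean higher high water (MHHW) tidal
datum.  The ground-elevation grid is referenced to a fixed vertical
datum; subtracting the tidal-offset surface converts it to elevation
above the sea level of the reference tidal epoch (midpoint 1992), and
subtracting multiples of the local rise-rate surface shifts it to the
sea level of any other year:

    rel(x, year) = E(x) - T(x) - r(x) * (year - 1992) / 1000

with E, T in meters and r in mm/yr.

An elevation hazard zone is the dry land strictly below a threshold z
(cells with rel < z, cell-center convention, water/wetland cells
excluded).  Mapped floodplain polygons are carried through as their own
zone types and split into coastal vs inland by comparing ground
elevation with the base flood elevation (BFE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grids import Grid, mask_area, polygonize_mask
from .synthetic import REFERENCE_YEAR

log = logging.getLogger(__name__)


@dataclass
class RelativeElevationGrid(Grid):
    """Elevation (m) relative to the sea level of a stated year."""

    year: int = REFERENCE_YEAR


@dataclass
class HazardZone:
    """A delineated hazard zone.

    For elevation zones the defining cell mask and its grid are kept
    alongside the dissolved polygons; point-membership queries then use
    the exact cell rule, which is consistent with the polygonization to
    within boundary ties.
    """

    geometry: shapely.Geometry
    zone_type: str  # "elevation" | "floodplain_100" | "floodplain_500"
    threshold_z_m: float | None = None
    sea_level_year: int | None = None
    coastal_flag: str = "n/a"  # "coastal" | "inland" | "n/a"
    mask: np.ndarray | None = field(default=None, repr=False)
    grid: Grid | None = field(default=None, repr=False)

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    def contains_points(self, x, y) -> np.ndarray:
        """Boolean membership of points (cell rule when available)."""
        if self.mask is not None and self.grid is not None:
            return self.grid.mask_at(self.mask, x, y)
        if self.geometry.is_empty:
            return np.zeros(np.shape(np.asarray(x)), dtype=bool)
        shapely.prepare(self.geometry)
        return shapely.contains_xy(self.geometry, np.asarray(x), np.asarray(y))


def relative_elevation_grid(elev: Grid, tidal: Grid, rate: Grid, year: int) -> RelativeElevationGrid:
    """Elevation relative to the sea level of ``year``.

    ``elev`` is ground elevation vs the fixed datum (m), ``tidal`` the
    height of reference-epoch sea level vs that datum (m), ``rate`` the
    local sea-level rise rate (mm/yr).  Nodata propagates from every
    input.  Raises ``ValueError`` if the grids are not co-registered.
    """
    for name, g in (("tidal", tidal), ("rate", rate)):
        if not elev.same_georef(g):
            raise ValueError(
                f"{name} grid not co-registered with elevation grid: "
                f"shapes {g.data.shape} vs {elev.data.shape}, "
                f"origins ({g.x0}, {g.y0}) vs ({elev.x0}, {elev.y0})"
            )
    rel = elev.data - tidal.data - rate.data * (year - REFERENCE_YEAR) / 1000.0
    nodata = None
    masks = [g.nodata for g in (elev, tidal, rate) if g.nodata is not None]
    if masks:
        nodata = np.logical_or.reduce(masks)
    return RelativeElevationGrid(rel, elev.x0, elev.y0, elev.cell, nodata, year=year)


def delineate_low_land(rel: RelativeElevationGrid, z: float, water_mask: np.ndarray) -> HazardZone:
    """Dry land strictly below ``z`` meters of the grid's sea level.

    Cell membership is by cell-center value with a strict inequality
    (exact ties at z are excluded); water-masked cells never enter the
    zone.  An all-nodata grid yields an empty zone with a warning.
    """
    if z <= 0:
        raise ValueError("threshold z must be positive")
    water_mask = np.asarray(water_mask, dtype=bool)
    if water_mask.shape != rel.data.shape:
        raise ValueError("water mask shape does not match grid")
    valid = rel.valid()
    if not valid.any():
        log.warning("all cells are nodata; returning an empty hazard zone")
    mask = (rel.data < z) & ~water_mask & valid
    return HazardZone(
        geometry=polygonize_mask(mask, rel),
        zone_type="elevation",
        threshold_z_m=float(z),
        sea_level_year=rel.year,
        coastal_flag="n/a",
        mask=mask,
        grid=rel,
    )


_FLOOD_TYPE = {"A": "floodplain_100", "X500": "floodplain_500"}


def classify_floodplain(flood_polys: pd.DataFrame, elev: Grid, bfe: float) -> list[HazardZone]:
    """Split mapped floodplains into coastal vs inland zones.

    Each input polygon (columns ``geometry``, ``category`` with category
    "A" = 100-year, "X500" = 500-year) is called *coastal* if the
    area-majority of its grid cells has ground elevation <= ``bfe``, the
    base flood elevation, and *inland* otherwise.  Polygons outside the
    grid extent default to inland with a warning.  Returns one
    :class:`HazardZone` per non-empty (category, coastal_flag) pair.
    """
    X, Y = elev.center_mesh()
    xf, yf = X.ravel(), Y.ravel()
    groups: dict[tuple[str, str], list[shapely.Geometry]] = {}
    for _, row in flood_polys.iterrows():
        geom, cat = row["geometry"], row["category"]
        if cat not in _FLOOD_TYPE:
            raise ValueError(f"unknown floodplain category {cat!r}")
        xmin, ymin, xmax, ymax = geom.bounds
        sel = (xf >= xmin) & (xf <= xmax) & (yf >= ymin) & (yf <= ymax)
        flag = "inland"
        if sel.any():
            shapely.prepare(geom)
            inside = shapely.contains_xy(geom, xf[sel], yf[sel])
            if inside.any():
                low = np.count_nonzero(elev.data.ravel()[sel][inside] <= bfe)
                flag = "coastal" if low * 2 > np.count_nonzero(inside) else "inland"
            else:
                log.warning("floodplain polygon covers no grid cell; classified inland")
        else:
            log.warning("floodplain polygon outside grid extent; classified inland")
        groups.setdefault((cat, flag), []).append(geom)
    zones = []
    for (cat, flag), geoms in sorted(groups.items()):
        zones.append(
            HazardZone(
                geometry=shapely.union_all(geoms),
                zone_type=_FLOOD_TYPE[cat],
                coastal_flag=flag,
            )
        )
    return zones


def idw_rate_grid(gauges: list[tuple[float, float, float]], like: Grid, power: float = 2.0) -> Grid:
    """Inverse-distance interpolation of tide-gauge rise rates (mm/yr).

    A convenience for building a rate surface from point gauge records;
    it is not a substitute for an official interpolated product.
    """
    if not gauges:
        raise ValueError("need at least one gauge")
    X, Y = like.center_mesh()
    num = np.zeros_like(X)
    den = np.zeros_like(X)
    exact = np.full(X.shape, np.nan)
    for gx, gy, rate in gauges:
        d2 = (X - gx) ** 2 + (Y - gy) ** 2
        hit = d2 == 0
        exact[hit] = rate
        with np.errstate(divide="ignore"):
            w = d2 ** (-power / 2.0)
        w[hit] = 0.0
        num += w * rate
        den += w
    out = num / np.where(den == 0, 1.0, den)
    out = np.where(np.isnan(exact), out, exact)
    return like.like(out)


def zone_area_check(zone: HazardZone) -> tuple[float, float]:
    """(polygon area, masked-cell area) — equal up to float rounding."""
    poly_area = zone.geometry.area
    cell_area = mask_area(zone.mask, zone.grid) if zone.mask is not None else float("nan")
    return float(poly_area), cell_area
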