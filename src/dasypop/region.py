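"""Shared containers for a study region.

A region bundles everything one pass of the exposure analysis needs:
census-block tables per decennial year, building footprints, the ground
elevation grid (relative to a fixed vertical datum), the tidal-offset
surface, the sea-level rise-rate surface, a water/wetland mask, mapped
floodplain polygons and — for synthetic regions only — person-level
ground truth.

Vector layers are plain :class:`pandas.DataFrame` objects with a
``geometry`` column of shapely objects; block tables follow a fixed
column convention (see :data:`BLOCK_COLUMNS`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grids import Grid, polygonize_mask

#: Population subgroups carried through every stage.  ``black`` means
#: non-Hispanic Black; ``hispanic`` means Hispanic of any race, so the
#: two subgroup classes are mutually exclusive while each overlaps
#: ``total``.
SUBGROUPS = ("total", "black", "hispanic")

#: Column that holds the population of each subgroup in a block table.
POP_COLUMN = {g: f"pop_{g}" for g in SUBGROUPS}

#: Required columns of a census-block table (one row per block).
BLOCK_COLUMNS = [
    "block_id",
    "county",
    "geometry",
    "pop_total",
    "pop_black",
    "pop_hispanic",
    "housing_units",
]


def validate_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    """Check a block table against the column convention and invariants."""
    missing = [c for c in BLOCK_COLUMNS if c not in blocks.columns]
    if missing:
        raise ValueError(f"block table missing columns: {missing}")
    for g in ("black", "hispanic"):
        if (blocks[POP_COLUMN[g]] > blocks["pop_total"]).any():
            raise ValueError(f"{g} population exceeds total in some block")
    return blocks


@dataclass
class RegionBundle:
    """A self-consistent region: inputs plus (synthetic) ground truth.

    Attributes
    ----------
    blocks : dict[int, DataFrame]
        Census-block table per census year.
    buildings : DataFrame
        One row per building: ``building_id, block_id, x, y, geometry``
        (geometry is the footprint polygon; x, y its centroid).
    elevation : Grid
        Ground elevation (m) relative to the fixed vertical datum.
    tidal : Grid
        Height (m) of reference-epoch sea level above the fixed datum.
    rise_rate : Grid
        Local relative sea-level rise rate, mm/yr.
    water : ndarray of bool
        Open-water / wetland mask on the elevation grid.
    floodplains : DataFrame
        Mapped floodplain polygons: ``geometry, category`` with category
        in {"A", "X500"} (100-year and 500-year zones).
    persons : dict[int, DataFrame]
        Ground-truth person points per census year (synthetic regions):
        ``person_id, x, y, block_id, building_id, black, hispanic``.
    metadata : dict
        Free-form provenance: config echo, seed, per-decade removal
        counts recorded by the migration step, ...
    """

    blocks: dict[int, pd.DataFrame]
    buildings: pd.DataFrame
    elevation: Grid
    tidal: Grid
    rise_rate: Grid
    water: np.ndarray
    floodplains: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["geometry", "category"]))
    persons: dict[int, pd.DataFrame] = field(default_factory=dict)
    gauges: pd.DataFrame | None = None
    metadata: dict[str, Any] = field(default_factory=dict)
    _water_poly: shapely.Geometry | None = field(default=None, repr=False)

    @property
    def census_years(self) -> list[int]:
        return sorted(self.blocks)

    @property
    def current_year(self) -> int:
        return max(self.blocks)

    def water_polygon(self) -> shapely.Geometry:
        """Dissolved polygon of the water mask (cached)."""
        if self._water_poly is None:
            self._water_poly = polygonize_mask(self.water, self.elevation)
        return self._water_poly

    def true_zone_count(self, year: int, in_zone, subgroup: str = "total") -> int:
        """Ground-truth person count inside a zone (synthetic regions).

        ``in_zone`` is a callable mapping (x, y) arrays to a boolean
        membership array, e.g. ``zone.contains_points``.
        """
        ppl = self.persons[year]
        inside = in_zone(ppl["x"].to_numpy(), ppl["y"].to_numpy())
        if subgroup == "total":
            return int(np.count_nonzero(inside))
        return int(ppl.loc[inside, subgroup].sum())


def assign_points_to_blocks(x, y, blocks: pd.DataFrame) -> np.ndarray:
    """block_id of the block polygon containing each point ("" if none).

    Points on a shared block edge are assigned to a single block
    (first spatial-index hit), never double-counted.
    """
    tree = shapely.STRtree(blocks["geometry"].to_numpy())
    pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    out = np.empty(len(pts), dtype=object)
    out[:] = ""
    pt_idx, blk_idx = tree.query(pts, predicate="intersects")
    ids = blocks["block_id"].to_numpy()
    seen: set[int] = set()
    for pi, bi in zip(pt_idx, blk_idx):
        if pi not in seen:
            out[pi] = ids[bi]
            seen.add(pi)
    return out


# ---------------------------------------------------------------------
# GeoJSON / CSV / manifest I/O


def write_geojson(df: pd.DataFrame, path: str | Path, geometry: str = "geometry") -> None:
    """Write a geometry-bearing DataFrame as a GeoJSON FeatureCollection."""
    feats = []
    for _, row in df.iterrows():
        props = {k: _jsonable(v) for k, v in row.items() if k != geometry}
        feats.append(
            {"type": "Feature", "geometry": mapping(row[geometry]), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def write_manifest(path: str | Path, entries: dict[str, Any]) -> None:
    """Key-value manifest, one ``key = value`` per line."""
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        out[k.strip()] = v.strip()
    return out


def save_bundle(bundle: RegionBundle, outdir: str | Path) -> None:
    """Write a bundle as plain-text layers (GeoJSON, ASCII grid, CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for year, blocks in bundle.blocks.items():
        write_geojson(blocks, outdir / f"blocks_{year}.geojson")
    write_geojson(bundle.buildings, outdir / "buildings.geojson")
    if len(bundle.floodplains):
        write_geojson(bundle.floodplains, outdir / "floodplains.geojson")
    for year, ppl in bundle.persons.items():
        ppl.to_csv(outdir / f"persons_{year}.csv", index=False)
    bundle.elevation.to_ascii(outdir / "elevation.asc")
    bundle.tidal.to_ascii(outdir / "tidal.asc")
    bundle.rise_rate.to_ascii(outdir / "rise_rate.asc")
    bundle.elevation.like(bundle.water.astype(float)).to_ascii(outdir / "water_mask.asc")
    if bundle.gauges is not None:
        bundle.gauges.to_csv(outdir / "gauges.csv", index=False)
    write_manifest(outdir / "manifest.txt", {
        "census_years": ",".join(str(y) for y in bundle.census_years),
        **{f"meta.{k}": v for k, v in bundle.metadata.items() if np.isscalar(v) or isinstance(v, str)},
    })


def load_bundle(indir: str | Path) -> RegionBundle:
    """Load a bundle previously written by :func:`save_bundle`."""
    indir = Path(indir)
    manifest = read_manifest(indir / "manifest.txt")
    years = [int(y) for y in manifest["census_years"].split(",")]
    blocks = {y: validate_blocks(read_geojson(indir / f"blocks_{y}.geojson")) for y in years}
    buildings = read_geojson(indir / "buildings.geojson")
    fp_path = indir / "floodplains.geojson"
    floodplains = read_geojson(fp_path) if fp_path.exists() else pd.DataFrame(columns=["geometry", "category"])
    persons = {}
    for y in years:
        p = indir / f"persons_{y}.csv"
        if p.exists():
            persons[y] = pd.read_csv(p)
    elevation = Grid.from_ascii(indir / "elevation.asc")
    tidal = Grid.from_ascii(indir / "tidal.asc")
    rise = Grid.from_ascii(indir / "rise_rate.asc")
    water = Grid.from_ascii(indir / "water_mask.asc").data > 0.5
    gauges_path = indir / "gauges.csv"
    gauges = pd.read_csv(gauges_path) if gauges_path.exists() else None
    meta = {k.removeprefix("meta."): v for k, v in manifest.items() if k.startswith("meta.")}
    return RegionBundle(
        blocks=blocks,
        buildings=buildings,
        elevation=elevation,
        tidal=tidal,
        rise_rate=rise,
        water=water,
        floodplains=floodplains,
        persons=persons,
        gauges=gauges,
        metadata=meta,
    )
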