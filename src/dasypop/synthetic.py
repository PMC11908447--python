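"""Synthetic coastal regions with person-level ground truth.

The generator emulates the statistical structure of a low-lying coastal
study area: counties tiled by rectangular census blocks, a gently
sloping elevation surface with smooth noise, an open-water fringe below
the reference-epoch sea level, buildings that preferentially avoid the
lowest ground, and people who live exactly at building locations.  Every
person is a point with known coordinates and subgroup flags, so any
zone-population quantity computed downstream can be checked against a
direct point-in-zone count.

Decade-to-decade dynamics reproduce the two features that matter for
trend accounting: census blocks are occasionally *split* between
censuses (people and buildings do not move), and people *emigrate* with
a probability that depends on county, elevation and subgroup.  Removal
events are logged in the bundle metadata so emigration accounting can be
validated against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .grids import Grid, polygonize_mask
from .region import RegionBundle, assign_points_to_blocks, validate_blocks

REFERENCE_YEAR = 1992  # midpoint of the tidal epoch the tidal surface refers to


@dataclass
class TerrainConfig:
    """Deterministic elevation surface: tilted plane + smooth seeded noise."""

    base_elev_m: float = -0.5  # elevation (fixed datum) at the x = 0 shoreline edge
    slope_m_per_km: float = 2.0  # plane rises inland along +x
    noise_amp_m: float = 0.25
    noise_wavelength_m: float = 900.0
    n_harmonics: int = 4


@dataclass
class MigrationConfig:
    """Per-decade emigration probabilities, conditioned on place and race.

    A person's removal probability for one decade is::

        p = county_mult * (base_rate + low_rate * 1[elev < low_elev_threshold_m] * m)

    where ``m`` is ``black_low_multiplier`` for Black persons and 1
    otherwise.  Setting ``black_low_multiplier > 1`` produces the
    subgroup-biased emigration that the disparity statistics are meant
    to recover.
    """

    base_rate: float = 0.02
    low_rate: float = 0.10
    low_elev_threshold_m: float = 1.0
    black_low_multiplier: float = 1.5
    county_multiplier: dict[str, float] = field(default_factory=dict)

    def removal_prob(self, county: np.ndarray, elev: np.ndarray, black: np.ndarray) -> np.ndarray:
        cm = np.array([self.county_multiplier.get(c, 1.0) for c in county])
        low = elev < self.low_elev_threshold_m
        mult = np.where(black.astype(bool), self.black_low_multiplier, 1.0)
        return np.clip(cm * (self.base_rate + self.low_rate * low * mult), 0.0, 1.0)


@dataclass
class SubgroupMix:
    """Per-county subgroup proportions plus an elevation gradient.

    ``county_black[c]`` / ``county_hispanic[c]`` give baseline
    proportions for county index ``c`` (cycled if there are more
    counties).  ``elevation_gradient`` adds to the Black proportion per
    meter a person lives *below* the county's mean dry-land elevation,
    mimicking racially uneven settlement of low ground.
    """

    county_black: tuple[float, ...] = (0.35, 0.10)
    county_hispanic: tuple[float, ...] = (0.10, 0.20)
    elevation_gradient: float = 0.04

    def validate(self) -> None:
        for pb, ph in zip(self.county_black, self.county_hispanic):
            if not (0 <= pb <= 1 and 0 <= ph <= 1 and pb + ph <= 1):
                raise ValueError("subgroup proportions must lie in [0,1] and sum to <= 1")


@dataclass
class FloodplainConfig:
    """Synthetic mapped floodplains: a coastal band plus an inland river band."""

    coastal_a_upper_m: float = 1.2  # A zone: 0 <= rel elevation < this
    coastal_x500_upper_m: float = 1.8
    river_halfwidth_a_m: float = 75.0
    river_halfwidth_x500_m: float = 125.0
    river_min_rel_elev_m: float = 2.5


@dataclass
class RegionConfig:
    """Everything needed to generate a region deterministically."""

    seed: int = 0
    n_counties: int = 2
    blocks_per_county: int = 100
    block_size_m: float = 250.0
    n_persons: int = 5000
    buildings_per_block_mean: float = 12.0
    cell_m: float = 25.0
    terrain: TerrainConfig = field(default_factory=TerrainConfig)
    tidal_offset_m: float = 0.2
    rise_rate_mm_per_yr: float = 4.0
    gauges: list[tuple[float, float, float]] | None = None  # (x, y, rate mm/yr)
    census_years: tuple[int, ...] = (1990, 2000, 2010, 2020)
    placement_bias: float = 0.7
    person_mode: str = "buildings"  # or "uniform" (adversarial for the building estimator)
    subgroup_mix: SubgroupMix = field(default_factory=SubgroupMix)
    migration: MigrationConfig = field(default_factory=MigrationConfig)
    split_prob: float = 0.05

    def validate(self) -> None:
        if self.n_counties < 1 or self.blocks_per_county < 1:
            raise ValueError("need at least one county and one block per county")
        if self.block_size_m <= 0 or self.cell_m <= 0:
            raise ValueError("degenerate geometry: block and cell sizes must be positive")
        if len(self.census_years) < 2:
            raise ValueError("need at least 2 census years")
        if any(b >= a for a, b in zip(self.census_years[1:], self.census_years)):
            raise ValueError("census_years must be strictly increasing")
        if not 0 <= self.placement_bias <= 1:
            raise ValueError("placement_bias must lie in [0, 1]")
        if self.person_mode not in ("buildings", "uniform"):
            raise ValueError(f"unknown person_mode {self.person_mode!r}")
        self.subgroup_mix.validate()

    # grid layout -----------------------------------------------------

    def block_grid_shape(self) -> tuple[int, int]:
        """(nbx, nby): blocks across (x) and along (y) within each county."""
        n = self.blocks_per_county
        nbx = int(np.sqrt(n))
        while n % nbx:
            nbx -= 1
        return nbx, n // nbx

    def extent(self) -> tuple[float, float]:
        nbx, nby = self.block_grid_shape()
        return nbx * self.block_size_m, self.n_counties * nby * self.block_size_m


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------
# terrain


def elevation_surface(config: RegionConfig, grid_shape: tuple[int, int]) -> Grid:
    """Build the ground-elevation grid: tilted plane + smooth seeded noise."""
    t = config.terrain
    ny, nx = grid_shape
    g = Grid(np.zeros((ny, nx)), 0.0, 0.0, config.cell_m)
    X, Y = g.center_mesh()
    z = t.base_elev_m + t.slope_m_per_km * X / 1000.0
    if t.noise_amp_m > 0 and t.n_harmonics > 0:
        rng = _rng(config.seed, 1)
        acc = np.zeros_like(X)
        for _ in range(t.n_harmonics):
            wl = t.noise_wavelength_m * rng.uniform(0.6, 1.6)
            theta = rng.uniform(0, 2 * np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            kx, ky = np.cos(theta) / wl, np.sin(theta) / wl
            acc += np.sin(2 * np.pi * (kx * X + ky * Y) + phase)
        z = z + t.noise_amp_m * acc / t.n_harmonics
    return g.like(z)


# ---------------------------------------------------------------------
# block frame


def _county_name(c: int) -> str:
    return f"county{c}"


def build_block_frame(config: RegionConfig) -> pd.DataFrame:
    """Rectangular blocks tiling each county; counties stacked along y."""
    nbx, nby = config.block_grid_shape()
    s = config.block_size_m
    rows = []
    for c in range(config.n_counties):
        y_off = c * nby * s
        for by in range(nby):
            for bx in range(nbx):
                rows.append(
                    {
                        "block_id": f"c{c}_b{by * nbx + bx:04d}",
                        "county": _county_name(c),
                        "geometry": box(bx * s, y_off + by * s, (bx + 1) * s, y_off + (by + 1) * s),
                    }
                )
    return pd.DataFrame(rows)


def _cells_in_rect(grid: Grid, bounds: tuple[float, float, float, float]):
    """Index arrays (i, j) of cells whose centers fall inside a rectangle."""
    xmin, ymin, xmax, ymax = bounds
    xc, yc = grid.x_centers(), grid.y_centers()
    j = np.flatnonzero((xc > xmin) & (xc < xmax))
    i = np.flatnonzero((yc > ymin) & (yc < ymax))
    ii, jj = np.meshgrid(i, j, indexing="ij")
    return ii.ravel(), jj.ravel()


# ---------------------------------------------------------------------
# buildings and persons


def _place_buildings(config: RegionConfig, blocks: pd.DataFrame, elev: Grid, water: np.ndarray) -> pd.DataFrame:
    """Place buildings on dry cells, biased away from low ground.

    With placement bias beta, each building picks its cell uniformly from
    the block's dry cells that lie strictly above the block's median dry
    elevation with probability beta, and from all dry cells otherwise.
    beta = 1 therefore puts no building below the block median; beta = 0
    is uniform over dry land.
    """
    rng = _rng(config.seed, 2)
    half = 4.0  # footprint half-side, m
    recs = []
    for _, blk in blocks.iterrows():
        ii, jj = _cells_in_rect(elev, blk.geometry.bounds)
        dry = ~water[ii, jj]
        ii, jj = ii[dry], jj[dry]
        n_b = rng.poisson(config.buildings_per_block_mean)
        if len(ii) == 0 or n_b == 0:
            continue
        e = elev.data[ii, jj]
        med = np.median(e)
        high = np.flatnonzero(e > med)
        if len(high) == 0:  # flat block: no cell strictly above the median
            high = np.arange(len(ii))
        use_high = rng.random(n_b) < config.placement_bias
        pick = np.where(
            use_high,
            high[rng.integers(0, len(high), n_b)],
            rng.integers(0, len(ii), n_b),
        )
        # jitter strictly inside the chosen cell so membership is unambiguous
        x = elev.x0 + (jj[pick] + 0.5 + rng.uniform(-0.3, 0.3, n_b)) * elev.cell
        y = elev.y0 + (ii[pick] + 0.5 + rng.uniform(-0.3, 0.3, n_b)) * elev.cell
        for k in range(n_b):
            recs.append(
                {
                    "building_id": f"{blk.block_id}-b{k:03d}",
                    "block_id": blk.block_id,
                    "x": x[k],
                    "y": y[k],
                    "geometry": box(x[k] - half, y[k] - half, x[k] + half, y[k] + half),
                }
            )
    return pd.DataFrame(recs)


def _place_persons(
    config: RegionConfig,
    blocks: pd.DataFrame,
    buildings: pd.DataFrame,
    elev: Grid,
    water: np.ndarray,
) -> pd.DataFrame:
    rng = _rng(config.seed, 3)
    n = config.n_persons
    if config.person_mode == "buildings":
        if len(buildings) == 0:
            raise ValueError("no buildings to host persons")
        idx = rng.integers(0, len(buildings), n)
        b = buildings.iloc[idx]
        ppl = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "x": b["x"].to_numpy(),
                "y": b["y"].to_numpy(),
                "block_id": b["block_id"].to_numpy(),
                "building_id": b["building_id"].to_numpy(),
            }
        )
    else:  # uniform over dry land, ignoring buildings (adversarial mode)
        cells, weights, ids = [], [], []
        for _, blk in blocks.iterrows():
            ii, jj = _cells_in_rect(elev, blk.geometry.bounds)
            dry = ~water[ii, jj]
            for i, j in zip(ii[dry], jj[dry]):
                cells.append((i, j))
                ids.append(blk.block_id)
        if not cells:
            raise ValueError("region has no dry land")
        pick = rng.integers(0, len(cells), n)
        cells_arr = np.array(cells)
        ci, cj = cells_arr[pick, 0], cells_arr[pick, 1]
        ppl = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "x": elev.x0 + (cj + 0.5 + rng.uniform(-0.49, 0.49, n)) * elev.cell,
                "y": elev.y0 + (ci + 0.5 + rng.uniform(-0.49, 0.49, n)) * elev.cell,
                "block_id": np.array(ids, dtype=object)[pick],
                "building_id": "",
            }
        )
    # subgroup flags
    mix = config.subgroup_mix
    county_idx = ppl["block_id"].str.extract(r"c(\d+)_")[0].astype(int).to_numpy()
    pb = np.array([mix.county_black[c % len(mix.county_black)] for c in county_idx])
    ph = np.array([mix.county_hispanic[c % len(mix.county_hispanic)] for c in county_idx])
    pelev = elev.values_at(ppl["x"].to_numpy(), ppl["y"].to_numpy())
    dry_mean = np.full(config.n_counties, np.nan)
    for c in range(config.n_counties):
        sel = county_idx == c
        if sel.any():
            dry_mean[c] = pelev[sel].mean()
    grad = mix.elevation_gradient * (dry_mean[county_idx] - pelev)
    rngg = _rng(config.seed, 4)
    hispanic = rngg.random(len(ppl)) < ph
    p_black = np.clip(pb + grad, 0.0, 0.95)
    black = (~hispanic) & (rngg.random(len(ppl)) < p_black)
    ppl["black"] = black.astype(int)
    ppl["hispanic"] = hispanic.astype(int)
    return ppl


def _count_blocks(
    blocks: pd.DataFrame, persons: pd.DataFrame, buildings: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate person points into a census-block table."""
    out = blocks[["block_id", "county", "geometry"]].copy()
    grp = persons.groupby("block_id")
    tot = grp.size()
    blk = grp["black"].sum()
    hisp = grp["hispanic"].sum()
    out["pop_total"] = out["block_id"].map(tot).fillna(0).astype(int)
    out["pop_black"] = out["block_id"].map(blk).fillna(0).astype(int)
    out["pop_hispanic"] = out["block_id"].map(hisp).fillna(0).astype(int)
    occupied = persons.loc[persons["building_id"] != "", "building_id"]
    units_by_block = (
        buildings.set_index("building_id")
        .loc[occupied.unique(), "block_id"]
        .value_counts()
        if len(occupied)
        else pd.Series(dtype=int)
    )
    if persons["building_id"].eq("").all():
        # uniform person mode: no occupied-building notion; use all buildings
        units_by_block = buildings.groupby("block_id").size()
    out["housing_units"] = out["block_id"].map(units_by_block).fillna(0).astype(int)
    return validate_blocks(out)


# ---------------------------------------------------------------------
# floodplains


def synthetic_floodplains(
    config: RegionConfig, elev: Grid, water: np.ndarray,
    fp: FloodplainConfig | None = None,
) -> pd.DataFrame:
    """Mapped-floodplain stand-in: coastal elevation bands + an inland river band."""
    fp = fp or FloodplainConfig()
    rel = elev.data - config.tidal_offset_m
    _, height = config.extent()
    Y = elev.center_mesh()[1]
    a_coast = (rel >= 0) & (rel < fp.coastal_a_upper_m) & ~water
    x5_coast = (rel >= fp.coastal_a_upper_m) & (rel < fp.coastal_x500_upper_m) & ~water
    river = np.abs(Y - height / 2.0) < fp.river_halfwidth_a_m
    river_x5 = (np.abs(Y - height / 2.0) < fp.river_halfwidth_x500_m) & ~river
    a_inland = river & (rel > fp.river_min_rel_elev_m) & ~water
    x5_inland = river_x5 & (rel > fp.river_min_rel_elev_m) & ~water
    rows = []
    for mask, cat in [
        (a_coast | a_inland, "A"),
        ((x5_coast | x5_inland) & ~(a_coast | a_inland), "X500"),
    ]:
        geom = polygonize_mask(mask, elev)
        for part in getattr(geom, "geoms", [geom]):
            if not part.is_empty:
                rows.append({"geometry": part, "category": cat})
    return pd.DataFrame(rows, columns=["geometry", "category"])


# ---------------------------------------------------------------------
# main entry points


def generate_region(config: RegionConfig) -> RegionBundle:
    """Generate the first-census-year region with ground truth.

    Deterministic in ``config.seed``.  Raises ``ValueError`` on invalid
    configuration (degenerate geometry, fewer than two census years, ...).
    """
    config.validate()
    width, height = config.extent()
    ny = int(round(height / config.cell_m))
    nx = int(round(width / config.cell_m))
    elev = elevation_surface(config, (ny, nx))
    tidal = elev.like(np.full((ny, nx), config.tidal_offset_m))
    if config.gauges:
        from .hazard import idw_rate_grid

        rate = idw_rate_grid(config.gauges, elev)
    else:
        rate = elev.like(np.full((ny, nx), config.rise_rate_mm_per_yr))
    water = (elev.data - tidal.data) < 0.0  # below reference-epoch sea level

    blocks = build_block_frame(config)
    buildings = _place_buildings(config, blocks, elev, water)
    persons = _place_persons(config, blocks, buildings, elev, water)
    year0 = config.census_years[0]
    table0 = _count_blocks(blocks, persons, buildings)

    floodplains = synthetic_floodplains(config, elev, water)
    gauges = (
        pd.DataFrame(config.gauges, columns=["x", "y", "rate_mm_per_yr"])
        if config.gauges
        else None
    )
    return RegionBundle(
        blocks={year0: table0},
        buildings=buildings,
        elevation=elev,
        tidal=tidal,
        rise_rate=rate,
        water=water,
        floodplains=floodplains,
        persons={year0: persons},
        gauges=gauges,
        metadata={"seed": config.seed, "config": asdict(config), "removed": {}},
    )


def advance_census(region: RegionBundle, decade_rules: MigrationConfig | None = None,
                   split_prob: float | None = None) -> RegionBundle:
    """Append the next configured census year: emigration then block splits.

    People are removed (never moved) with the per-decade probability from
    ``decade_rules`` (defaults to the generating config's migration
    rules); removal counts per county and subgroup are logged under
    ``metadata['removed'][year]``.  A fraction ``split_prob`` of blocks
    is split in half; persons and buildings stay put and are re-assigned
    to the child blocks by containment, so splits never change any
    building-based aggregate.  Mutates and returns ``region``.
    """
    cfgd = region.metadata["config"]
    years = list(cfgd["census_years"])
    cur = region.current_year
    later = [y for y in years if y > cur]
    if not later:
        raise ValueError(f"no census year configured after {cur}")
    nxt = later[0]
    decade_idx = years.index(nxt)
    seed = region.metadata["seed"]
    rng = _rng(seed, 100 + decade_idx)

    mig = decade_rules
    if mig is None:
        mig = MigrationConfig(**cfgd["migration"])
    if split_prob is None:
        split_prob = cfgd["split_prob"]

    ppl = region.persons[cur]
    county = ppl["block_id"].str.extract(r"(c\d+)_")[0].map(lambda s: s.replace("c", "county", 1))
    elev = region.elevation.values_at(ppl["x"].to_numpy(), ppl["y"].to_numpy())
    p = mig.removal_prob(county.to_numpy(), elev, ppl["black"].to_numpy())
    removed = rng.random(len(ppl)) < p
    removed_df = ppl.loc[removed].copy()
    survivors = ppl.loc[~removed].copy()
    region.metadata["removed"][nxt] = {
        "n": int(removed.sum()),
        "persons": removed_df,
    }

    # Split a fraction of blocks; earlier-year tables keep the old frame.
    # A split separates the developed part (all buildings, hence all
    # persons) from an empty remainder, the way later censuses subdivide
    # a block into a built-up and an undeveloped block; blocks whose
    # buildings leave no gap along either axis are left unsplit.
    prev_blocks = region.blocks[cur]
    b_block = assign_points_to_blocks(
        region.buildings["x"].to_numpy(), region.buildings["y"].to_numpy(), prev_blocks
    )
    new_rows = []
    do_split = rng.random(len(prev_blocks)) < split_prob
    min_gap = 1.0  # m of empty land needed between buildings and the cut
    for (_, blk), split in zip(prev_blocks.iterrows(), do_split):
        children = None
        if split:
            xmin, ymin, xmax, ymax = blk.geometry.bounds
            sel = b_block == blk.block_id
            bx = region.buildings.loc[sel, "x"].to_numpy()
            by = region.buildings.loc[sel, "y"].to_numpy()
            for coord, lo, hi, vertical in ((bx, xmin, xmax, True), (by, ymin, ymax, False)):
                if len(coord) == 0:
                    cut = (lo + hi) / 2
                elif coord.max() < hi - min_gap:
                    cut = (coord.max() + hi) / 2
                elif coord.min() > lo + min_gap:
                    cut = (lo + coord.min()) / 2
                else:
                    continue
                if vertical:
                    children = (box(xmin, ymin, cut, ymax), box(cut, ymin, xmax, ymax))
                else:
                    children = (box(xmin, ymin, xmax, cut), box(xmin, cut, xmax, ymax))
                break
        if children is None:
            new_rows.append({"block_id": blk.block_id, "county": blk.county, "geometry": blk.geometry})
        else:
            for suffix, g in zip(("_a", "_b"), children):
                new_rows.append({"block_id": blk.block_id + suffix, "county": blk.county, "geometry": g})
    frame = pd.DataFrame(new_rows)

    survivors = survivors.copy()
    survivors["block_id"] = assign_points_to_blocks(
        survivors["x"].to_numpy(), survivors["y"].to_numpy(), frame
    )
    table = _count_blocks(frame, survivors, region.buildings)
    region.blocks[nxt] = table
    region.persons[nxt] = survivors.reset_index(drop=True)
    return region


def generate_history(config: RegionConfig) -> RegionBundle:
    """Generate a region and advance it through all configured censuses."""
    region = generate_region(config)
    for _ in config.census_years[1:]:
        advance_census(region)
    return region
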