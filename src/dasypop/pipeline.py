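"""End-to-end orchestration: region -> zones -> estimates -> accounting.

A run is driven by a single declarative YAML config (see
``examples/synthetic_demo.yaml``).  Every stage reads files or in-memory
products of earlier stages and writes plain-text outputs (GeoJSON,
ASCII grids, CSV) plus a key-value manifest recording the config hash,
seed and library versions, so a rerun with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dasymetric import METHODS, block_zone_fractions, estimate_zone_population, partially_vulnerable_census
from .disparity import emigration_disparity, residence_disparity
from .hazard import classify_floodplain, delineate_low_land, relative_elevation_grid
from .region import (POP_COLUMN, SUBGROUPS, RegionBundle, load_bundle, save_bundle,
                     write_geojson, write_manifest)
from .survey import StratumRules, combined_ratio_estimate, cv_report, draw_sample, stratify_blocks
from .synthetic import MigrationConfig, RegionConfig, SubgroupMix, TerrainConfig, generate_history
from .trends import county_apparent_migration, decompose_change, zone_population_series

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "run_output"
    input_dir: str | None = None  # load a saved bundle instead of generating
    region: dict = field(default_factory=dict)  # RegionConfig overrides
    z_thresholds: list[float] = field(default_factory=lambda: [1.0])
    sea_level_years: list[int] | None = None  # default: the census years
    bfe_m: float = 2.0
    methods: list[str] = field(default_factory=lambda: ["uniform", "building"])
    partial_threshold: float = 0.005  # "all or part" diagnostic cutoff
    emigration_flag_pct: float = 1.0
    validate: bool = False
    sample_fraction: float = 0.3  # of each stratum, when validating
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def region_config(self) -> RegionConfig:
        kw = dict(self.region)
        for key, sub in (("terrain", TerrainConfig), ("migration", MigrationConfig),
                         ("subgroup_mix", SubgroupMix)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        if "census_years" in kw:
            kw["census_years"] = tuple(kw["census_years"])
        kw.setdefault("seed", self.seed)
        return RegionConfig(**kw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = asdict(self)
        for incidental in ("outdir", "log_level"):
            d.pop(incidental, None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


STAGES = ("generate", "zones", "estimate", "series", "emigration", "disparity", "validate")


def run_pipeline(config: RunConfig, until: str | None = None) -> dict:
    """Execute the pipeline stages in order; returns in-memory products.

    ``until`` stops after the named stage (inclusive); later stages are
    skipped.  On a stage failure the run aborts with the stage name and
    earlier outputs are preserved on disk.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages are {STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    products: dict = {}
    done: list[str] = []

    def finished(stage: str) -> bool:
        done.append(stage)
        return until == stage

    stage = "generate"
    try:
        if config.input_dir:
            bundle = load_bundle(config.input_dir)
        else:
            bundle = generate_history(config.region_config())
            save_bundle(bundle, out / "region")
        products["bundle"] = bundle
        if finished(stage):
            return _finish(config, out, products, done)

        stage = "zones"
        sl_years = config.sea_level_years or bundle.census_years
        zones: dict[float, dict[int, object]] = {}
        for z in config.z_thresholds:
            zones[z] = {}
            for sly in sl_years:
                rel = relative_elevation_grid(bundle.elevation, bundle.tidal, bundle.rise_rate, sly)
                zones[z][sly] = delineate_low_land(rel, z, bundle.water)
            zdf = pd.DataFrame(
                [
                    {
                        "geometry": zn.geometry,
                        "zone_type": zn.zone_type,
                        "threshold_z_m": zn.threshold_z_m,
                        "sea_level_year": zn.sea_level_year,
                        "coastal_flag": zn.coastal_flag,
                    }
                    for zn in zones[z].values()
                ]
            )
            write_geojson(zdf, out / f"zones_z{z:g}.geojson")
        flood_zones = []
        if len(bundle.floodplains):
            flood_zones = classify_floodplain(bundle.floodplains, bundle.elevation, config.bfe_m)
            write_geojson(
                pd.DataFrame(
                    [
                        {"geometry": zn.geometry, "zone_type": zn.zone_type,
                         "coastal_flag": zn.coastal_flag}
                        for zn in flood_zones
                    ]
                ),
                out / "zones_floodplain.geojson",
            )
        products["zones"] = zones
        products["flood_zones"] = flood_zones
        if finished(stage):
            return _finish(config, out, products, done)

        stage = "estimate"
        water_poly = bundle.water_polygon()
        terminal = bundle.current_year
        blocks = bundle.blocks[terminal]
        estimates = {}
        for z in config.z_thresholds:
            zone = zones[z][sl_years[-1]]
            fr = block_zone_fractions(blocks, zone, bundle.buildings, water_poly)
            for method in config.methods:
                est = estimate_zone_population(
                    blocks, zone, bundle.buildings, method, water_poly, fractions=fr
                )
                est.to_csv(out / f"estimate_z{z:g}_{method}_{terminal}.csv")
                estimates[(z, method)] = est
            diag = partially_vulnerable_census(
                blocks, zone, bundle.buildings, water_poly,
                threshold=config.partial_threshold, fractions=fr,
            )
            pd.DataFrame([diag]).to_csv(out / f"diagnostic_z{z:g}_{terminal}.csv", index=False)
        products["estimates"] = estimates
        if finished(stage):
            return _finish(config, out, products, done)

        stage = "series"
        z0 = config.z_thresholds[0]
        method0 = "building" if "building" in config.methods else config.methods[0]
        series = zone_population_series(
            bundle.blocks, zones[z0], bundle.buildings, method=method0, water_poly=water_poly
        )
        series.data.to_csv(out / f"series_z{z0:g}_{method0}.csv", index=False)
        years = series.census_years
        decomp = decompose_change(series, years[0], years[-1])
        pd.DataFrame([decomp]).to_csv(out / "decomposition.csv", index=False)
        products["series"] = series
        products["decomposition"] = decomp
        if finished(stage):
            return _finish(config, out, products, done)

        stage = "emigration"
        base_year = bundle.census_years[0]
        county_pops = (
            bundle.blocks[base_year]
            .groupby("county")[[POP_COLUMN[g] for g in SUBGROUPS]]
            .sum()
            .reset_index()
        )
        emig = county_apparent_migration(series, county_pops, config.emigration_flag_pct)
        emig.table.to_csv(out / "emigration_by_county.csv", index=False)
        pd.DataFrame([emig.national]).to_csv(out / "emigration_national.csv", index=False)
        products["emigration"] = emig
        if finished(stage):
            return _finish(config, out, products, done)

        stage = "disparity"
        disparity_rows = []
        term_blocks = bundle.blocks[terminal].groupby("county")[[POP_COLUMN[g] for g in SUBGROUPS]].sum()
        zone = zones[z0][sl_years[-1]]
        fr = block_zone_fractions(bundle.blocks[terminal], zone, bundle.buildings, water_poly)
        est = estimate_zone_population(
            bundle.blocks[terminal], zone, bundle.buildings, method0, water_poly, fractions=fr
        )
        zone_by_county = est.by_county()
        base_by_county = bundle.blocks[base_year].groupby("county")[[POP_COLUMN[g] for g in SUBGROUPS]].sum()
        for g in ("black", "hispanic"):
            res_tbl = pd.DataFrame(
                {
                    "zone_subgroup": zone_by_county[f"est_{g}"],
                    "zone_total": zone_by_county["est_total"],
                    "county_subgroup": term_blocks[POP_COLUMN[g]],
                    "county_total": term_blocks[POP_COLUMN["total"]],
                }
            ).fillna(0.0)
            res = residence_disparity(res_tbl, g)
            disparity_rows.append(asdict(res))
            emig_tbl = emig.table.set_index("county")
            per_county = pd.DataFrame(
                {
                    "emig_subgroup": (-emig_tbl.get(f"change_full_{g}", pd.Series(dtype=float))).clip(lower=0),
                    "emig_total": (-emig_tbl["change_full"]).clip(lower=0),
                    "county_subgroup": base_by_county[POP_COLUMN[g]],
                    "county_total": base_by_county[POP_COLUMN["total"]],
                }
            ).fillna(0.0)
            em = emigration_disparity(
                {"total": emig.national["total"], g: emig.national.get(g, 0.0)},
                {
                    "total": float(base_by_county[POP_COLUMN["total"]].sum()),
                    g: float(base_by_county[POP_COLUMN[g]].sum()),
                },
                g,
                per_county=per_county,
            )
            disparity_rows.append(asdict(em))
        disparity_df = pd.DataFrame(disparity_rows)
        disparity_df.to_csv(out / "disparity.csv", index=False)
        products["disparity"] = disparity_df
        if finished(stage):
            return _finish(config, out, products, done)

        if config.validate or until == "validate":
            stage = "validate"
            if not bundle.persons:
                raise ValueError("validation requires ground-truth persons (synthetic bundle)")
            zone = zones[z0][sl_years[-1]]
            ppl = bundle.persons[terminal]
            in_zone = zone.contains_points(ppl["x"].to_numpy(), ppl["y"].to_numpy())
            truth = ppl.loc[in_zone].groupby("block_id").size()
            fr = block_zone_fractions(bundle.blocks[terminal], zone, bundle.buildings, water_poly)
            strata = stratify_blocks(bundle.blocks[terminal], fr, StratumRules())
            sizes = {
                lab: max(2, int(round(config.sample_fraction * n)))
                for lab, n in strata["stratum"].value_counts().items()
            }
            sizes = {lab: min(sz, int((strata["stratum"] == lab).sum())) for lab, sz in sizes.items()}
            rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 77])
            sample = draw_sample(strata, sizes, rng)
            reports = {}
            for method in config.methods:
                est = estimate_zone_population(
                    bundle.blocks[terminal], zone, bundle.buildings, method, water_poly, fractions=fr
                )
                est_by_block = est.per_block.set_index("block_id")["est_total"]
                s = sample.copy()
                s["observed"] = s["block_id"].map(truth).fillna(0.0)
                s["estimated"] = s["block_id"].map(est_by_block).fillna(0.0)
                ratio = combined_ratio_estimate(
                    s,
                    strata["stratum"].value_counts().to_dict(),
                    estimated_total=float(est_by_block.loc[strata["block_id"]].sum()),
                )
                reports[method] = ratio
            cvs = cv_report(reports)
            cvs.to_csv(out / "validation_cv.csv", index=False)
            products["validation"] = reports
            done.append("validate")
    except Exception:
        log.error("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        raise

    return _finish(config, out, products, done)


def _finish(config: RunConfig, out: Path, products: dict, done: list[str]) -> dict:
    write_manifest(
        out / "run_manifest.txt",
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "dasypop_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "stages": ",".join(done),
        },
    )
    return products
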