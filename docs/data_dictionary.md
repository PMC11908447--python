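# Data dictionary for pipeline CSV outputs

All geometry is in a projected, meter-based planar coordinate system.
Populations are real-valued internally; `*_rounded` columns are the
report-time integer versions.

## `estimate_z<z>_<method>_<year>.csv` — per-block zone estimates

| column | meaning |
| --- | --- |
| `block_id` | census-block identifier |
| `county` | county identifier |
| `dry_area_m2` | block area excluding open water / wetland, m² |
| `area_in_zone_m2` | dry-land area inside the hazard zone, m² |
| `n_buildings` | buildings whose footprint centroid lies in the block |
| `buildings_in_zone` | of those, buildings with centroid in the zone |
| `frac_area` | `area_in_zone_m2 / dry_area_m2` (0 when no dry land) |
| `frac_buildings` | `buildings_in_zone / n_buildings` (empty when no buildings) |
| `zero_dry` | flag: block has no dry land |
| `frac_used` | fraction actually applied (building method falls back to `frac_area` in buildingless partial blocks) |
| `pop_total`, `pop_black`, `pop_hispanic` | census block populations |
| `est_total`, `est_black`, `est_hispanic` | `pop_* x frac_used` |
| `est_*_rounded` | nearest-integer report values |

## `diagnostic_z<z>_<year>.csv` — partially vulnerable block census

`n_blocks_entirely`, `n_blocks_all_or_part`: counts of blocks entirely
in the zone and with at least 0.5% of dry land in the zone;
`pop_entirely_<g>`, `pop_all_or_part_<g>`: the populations of those
block classes per subgroup.

## `series_z<z>_<method>.csv` — decomposition series (tidy)

`census_year`, `sea_level_year`, `county`, `subgroup`, `population`:
the estimated population of census year *c* inside the zone defined by
the sea level of year *s*.

## `decomposition.csv`

`delta_census` (people changed, zone fixed at the terminal year),
`delta_sea_level` (zone changed, census fixed at the terminal year),
`actual` (diagonal change), `cross_term` (interaction; the three
components satisfy `actual = delta_census + delta_sea_level - cross_term`).

## `emigration_by_county.csv`

One row per county: per-decade changes (`1990s`, ...), `change_full`
(their exact sum), `change_full_black`, `change_full_hispanic`,
`pct_total` / `pct_black` / `pct_hispanic` (full-period change as % of
the county's base-year population; positive when the population grew)
and `flagged` (|`pct_total`| above the configured threshold).

## `emigration_national.csv`

Per subgroup, the apparent-emigration total: the sum of full-period
changes over the counties where that subgroup's change is negative
(hence always ≤ 0).

## `disparity.csv`

One row per (subgroup, measure): `share_zone` (subgroup share of the
zone population or of emigration), `share_reference` (subgroup share of
the reference population — terminal census for residence, base year for
emigration), `nationwide_ratio`, `county_weighted_ratio`.

## `validation_cv.csv`

One row per method: combined ratio `ratio` and its `se`, `cv`
(= se/ratio, read as a 66% confidence range), `adjusted_total` (method
total × ratio), `adjusted_se`, the ±1 se interval bounds, and
`excludes_one` (interval excludes ratio 1).
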