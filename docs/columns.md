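# Column dictionary

All files are UTF-8 CSV, comma-separated, `.` decimal point. Missing values
are empty cells — never 0, never sentinels. Unknown extra columns are
carried through untouched.

## Site table (schema version 1)

| column | type | unit | notes |
|---|---|---|---|
| site_id | string | — | required; unique per site |
| longitude | float | decimal degrees | optional, ∈ [−180, 180] |
| latitude | float | decimal degrees | optional, ∈ [−90, 90] |
| region | string | — | ocean-basin label, e.g. `asia_pacific` |
| pathway | enum | — | required; `reforestation`, `afforestation`, or `control` |
| age_years | float | years | required, ≥ 0; interval values like `10-25` are rejected |
| species | string | — | `;`-separated binomials |
| prior_land_use | string | — | pairs control rows to a pathway (`abandoned_pond` / `mudflat`) |
| agc | float | Mg C ha⁻¹ | aboveground biomass carbon, ≥ 0 |
| bgc | float | Mg C ha⁻¹ | belowground biomass carbon, ≥ 0 |
| scs | float | Mg C ha⁻¹ | sediment carbon to 1 m, ≥ 0 |
| tecs | float | Mg C ha⁻¹ | must equal agc+bgc+scs within max(0.5, 1%) when all present |
| map_mm | float | mm | mean annual precipitation |
| mat_c | float | °C | mean annual temperature |
| salinity_psu | float | psu | porewater salinity |
| toc_pct | float | % | sediment total organic carbon |
| tn_pct | float | % | sediment total nitrogen |
| source_id | string | — | source-article key; merge articles sharing a site upstream |

## Sediment profile table (long format)

| column | type | unit |
|---|---|---|
| site_id | string | — |
| top_cm | float | cm (0 at surface; layers contiguous, in order) |
| bottom_cm | float | cm (> top_cm) |
| soc_pct | float | % ∈ [0, 100] |
| bd_g_cm3 | float | g cm⁻³ (> 0) |

## Country-area table

| column | type | unit | notes |
|---|---|---|---|
| country | string | — | required |
| eez_id | string | — | required; (country, eez_id) unique |
| zone | string | — | geographic zone, used to fill unknown drivers |
| erosion | float | ha | loss to coastal erosion (infeasible to restore) |
| settlement | float | ha | loss to settlement (infeasible to restore) |
| commodities | float | ha | aquaculture/agriculture conversion |
| clearing | float | ha | clear-cutting |
| extreme_climate | float | ha | storm/climate mortality |
| unknown | float | ha | unattributed; redistribute via `fill_unknown_drivers` |
| rollout_years | int | years | optional; per-country duration for the varying-rates scenario (5/10/20) |

## Results table (written by `write_results`)

`scope, country, scenario, pathway, area_ha, agc_tg, bgc_tg, scs_tg,
total_tg, ci_lo_tg, ci_hi_tg` — Tg CO₂-eq at 6 decimals; a write-then-read
round trip reproduces values exactly at that precision.
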