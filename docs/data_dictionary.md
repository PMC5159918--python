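# Data dictionary (schema v1)

All tables are UTF-8 CSV with a header row. Missing values are empty
fields; booleans are `True`/`False`. Depths are cm below the soil
surface with half-open extents `[top, bottom)`.

## sites.csv

| column | type | description |
|---|---|---|
| site_id | str | unique site identifier |
| reporting_group | enum | one of the 10 NWCA Reporting Groups (ALL-EW, ALL-EH, EMU-PRLW, EMU-PRLH, CPL-PRLW, CPL-PRLH, IPL-PRLW, IPL-PRLH, W-PRLW, W-PRLH) |
| region | enum | Tidal Saline / EMU / Coastal Plains / Interior Plains / West; must match the group prefix |
| wetland_type | enum | EH, EW, PRL-EM, PRL-SS, PRL-FO, PRL-f, PRL-UBAB |
| hgm_class | str | hydrogeomorphic class assigned in the field |
| tidal_saline | bool | true iff reporting_group starts with `ALL-` |
| weight_ha | float > 0 | hectares represented (inverse inclusion probability × unit area); required positive for probability sites |
| probability_site | bool | false for hand-picked sites (calibration only, never estimation) |
| dist_agriculture … dist_alien_plant_cover | float ≥ 0 | the ten disturbance indices (see `wetcarbon.model.DISTURBANCE_MEASURES` for the exact column order) |

## horizons.csv

| column | type | description |
|---|---|---|
| site_id | str | joins to sites.csv |
| horizon_order | int ≥ 1 | 1 = surface; horizons of a site must be contiguous in depth |
| top_depth_cm / bottom_depth_cm | float | bottom > top; each top equals the previous bottom |
| organic_flag | bool | field texture indicates organic soil (peat/muck/mucky peat) |
| total_c_pct / inorg_c_pct / soc_pct | float in [0,100] or empty | soc is recomputed as max(0, total − inorganic) whenever both are present |
| bd_g_cm3 | float > 0 or empty | bulk density |
| bd_source | enum | measured / modelled / imputed_adjacent |
| ec / cec | float ≥ 0 or empty | electrical conductivity, cation exchange capacity |
| sand_pct / silt_pct / clay_pct | float in [0,100] or empty | sum ≤ 100 when all present |
| thin_flag | bool | thickness < 8 cm; described but not sampled |

## estimates.csv

One row per subpopulation × depth range: `subpopulation, depth_lo_cm,
depth_hi_cm, mean_tC_ha, se_mean, total_PgC, se_total, n_sites,
area_Mha`. Scaled (target-population) rows carry the suffix `|target`
in `subpopulation` and empty standard errors.

## per_site.csv (pipeline output)

`site_id, reporting_group, region, carbon_type (blue/teal), soil_class
(organic/mineral), disturbance_class (least/intermediate/most or
empty), probability_site, weight_ha`, then one
`density_<lo>_<hi>_tC_ha` column per configured depth range (empty when
the profile does not cover the range).
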