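# Data dictionary

All tables are CSV, UTF-8, '.' decimal, one header row. Rasters are
ESRI ASCII grids (heights in m, NODATA −9999, origin upper-left,
0-based cell indexing); point clouds are XYZ CSV; polygons GeoJSON.
Areas are hectares, heights meters, logs natural.

## compartments.csv
| column | meaning |
|---|---|
| compartment_id | unique stand identifier |
| management | detailed management type (e.g. "Scots pine monoculture") |
| age_class | detailed age band ("Restock" … "Mature", "Mixed ages", "Not applicable") |
| age_years | stand age in years (empty for mixed / not applicable) |
| area_ha | compartment area, ha |

## survey.csv
| column | meaning |
|---|---|
| compartment_id, species_id | keys |
| visit | 1 or 2 |
| count | birds recorded on that visit (zero rows may be omitted) |

At most one row per (compartment_id, species_id, visit).

## traits.csv
`species_id`, `body_mass_g` (continuous), `migratory_status`,
`nest_site`, `diet`, `foraging_strata` (categorical).

## detectability.csv
`species_id`, `detectability` — per-visit detection constant in (0, 1].

## structural_metrics.csv
One row per compartment. `top_canopy_height_<r>`, `gap_fraction_<r>`,
`horizontal_heterogeneity_<r>` for r in 0p5m, 2m, 5m, 10m (resolution
tag replaces '.' with 'p'); `vertical_evenness`, `shrub_density`,
`canopy_density` from the 10-m PAD profile.

## groups.csv
| column | meaning |
|---|---|
| group_id | analysis-row identifier |
| management, age_class | detailed grouping categories |
| management_simplified | Conifer / Broadleaved / Mixture / Open-other |
| age_simplified | Restock-pre-thicket / Thicket-pole / Mature / Mixed / Not applicable |
| n_members | compartments in the group (≥ 10) |
| total_area_ha, log_total_area | summed member area and its natural log |
| *metric columns* | unweighted means of member structural metrics |

## group_abundance.csv
Group × species matrix of detectability-corrected mean maximum counts.

## diversity.csv
Per group: `species_richness`, `shannon` (nats), `fric`, `feve`,
`fdiv`, `fdis`, plus `<metric>_norm` columns where a Box-Cox transform
was applied.

## resolution_choices.csv
`metric`, `variable`, `resolution`, `percent_independent`, `chosen` —
the scale-optimization diagnostics per response × multi-resolution
variable.

## hp_results.csv
`metric`, `variable`, `independent`, `joint`, `percent_independent`,
`r2_full` — the final nine-variable partition per response.

## collinearity.csv, selected_variables.csv
Pairwise association matrices per metric, and the selected subset plus
any aliased (dropped) design columns.

## model_coefficients.csv, anova.csv
OLS estimates (`estimate`, `se`, `p` per coefficient; baselines
conifer and mixed ages) and the type-2 ANOVA table (`sum_sq`, `df`,
`F`, `p` per term, plus residuals).

## truth.json, manifest.json
Generator ground truth (never read by the pipeline) and the run
manifest: seed, config hash, per-file SHA-256 checksums.
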