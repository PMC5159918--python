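# wetcarbon

Design-based accounting of wetland soil carbon stocks, in the style of
the US EPA's 2011 National Wetland Condition Assessment (NWCA): from
field-described soil horizons and survey weights to population-level
estimates of carbon density (tC ha⁻¹) and total stock (PgC) by depth,
region, blue/teal carbon type, organic/mineral soil class and
disturbance condition.

It is written for ecologists and survey statisticians who work with
probability-sample wetland (or other soil) monitoring data and want a
tested, reproducible pipeline rather than one-off scripts.

## What it computes

* **Horizon carbon density** — `rho_c = A · d_l · rho_d · C` (g m⁻²)
  with `A = 10,000 cm² m⁻²`, layer thickness `d_l` (cm), bulk density
  `rho_d` (g cm⁻³) and SOC fraction `C`; profiles are sliced into 1-cm
  increments to 120 cm so stocks aggregate over any depth range
  (100 g m⁻² = 1 tC ha⁻¹).
* **QC rules** — missing horizon carbon filled from adjacent horizons;
  bulk densities above the 2.0 g cm⁻³ measurable ceiling, differing
  from the model by >40%, or missing are replaced by modelled values.
* **Bulk-density model** — gradient-boosted regression trees on ten
  horizon/site covariates with a 70/30 holdout R² and per-predictor
  relative importance summing to 100%.
* **Soil classification** — histosol-style rules (organic to ≥40 cm;
  ≥40 organic cm in the top 80; shallow-impenetrable 2/3 rule) and
  blue (tidal saline) vs teal (freshwater inland) carbon typing.
* **Disturbance screening** — least / intermediate / most classes from
  per-reporting-group thresholds over ten stressor indices, with the
  most-thresholds calibrated so ~20–30% of screened sites are most
  disturbed.
* **Design-based estimation** — Horvitz–Thompson totals and ratio
  means with with-replacement standard errors from inverse-inclusion
  weights in hectares, plus proportional scaling from the inference
  area to a larger target frame.
* **Synthetic populations** — a generator that emulates the survey's
  data features (SOC depth-decay, bulk-density–SOC relation, ~25% thin
  unsampled horizons, ~30% missing bulk density, unequal-probability
  weights) with exact ground truth, so every stage is testable offline.

## Worked example

```python
from wetcarbon import run_pipeline

result = run_pipeline({"seed": 1, "target_area_Mha": 38.4,
                       "bd_model": {"n_trees": 500, "shrinkage": 0.05,
                                    "max_tree_depth": 3}}, "runs/demo")
```

`examples/06_estimate_stocks.py` prints, from exactly this run:

```
national stocks (inference population):
  depth(cm)   mean tC/ha        total PgC     n
    0-30       155 ± 3        3.95 ± 0.15   200
   30-60       127 ± 4        2.99 ± 0.15   183
   60-90        92 ± 5        1.91 ± 0.13   163
   90-120       77 ± 7        1.40 ± 0.14   143
    0-120      444 ± 16       8.11 ± 0.55   143
blue 1.58 PgC on 3.1 Mha; teal 6.53 PgC on 15.1 Mha
scaled to the 38.4 Mha target frame: 8.11 -> 12.25 PgC (mean density unchanged; no SE for the unsampled area)
```

Each row is an area-weighted estimate over the synthetic probability
sample: the mean carbon density and total stock for that depth
increment with standard errors, and the number of sites whose profile
fully covers the increment (n shrinks with depth because some profiles
stop on an impenetrable layer). The final line extrapolates the total
to a larger target frame under the assumption that unsampled area
behaves like sampled area.

The other scripts in `examples/` each demonstrate one capability —
simulation, QC + bulk-density modelling, accounting, classification,
screening, and the published-summary ratios — and print a line or two
explaining their numbers. A thin CLI mirrors the stages
(`wetcarbon simulate|qc|fit-bd|account|classify|screen|estimate|run|report`).

## Layout

```
src/wetcarbon/   model, io, simulate, qc, bdmodel, accounting,
                 classify, disturbance, estimation, published,
                 pipeline, cli
tests/           pytest suite (unit, property and acceptance tests)
examples/        one narrative script per capability
docs/            methods.md (models, assumptions, limitations),
                 data_dictionary.md (CSV schemas)
scripts/         acceptance.py
```
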