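# Methods

## The accounting model

A wetland soil profile is an ordered, contiguous stack of described
horizons with half-open depth extents `[top, bottom)` in cm below the
surface. The carbon density of a layer is

    rho_c = A · d_l · rho_d · C            [g m⁻²]

with `A = 10,000 cm² m⁻²`, layer thickness `d_l` (cm), bulk density
`rho_d` (g cm⁻³) and SOC mass fraction `C` (SOC is total minus inorganic
carbon, clipped at zero — carbonate-rich samples can produce small
negative differences, which are clipped with a logged warning). Because
horizon depths differ between profiles, each profile is resolved onto
1-cm increments to 120 cm (`accounting.slice_profile`), assuming
within-horizon homogeneity. Non-integer horizon boundaries are handled
by thickness-weighting the horizons overlapping each slice, which makes
slicing conserve per-horizon totals exactly (to float rounding; tests
assert 1e-9 relative). A depth range contributes for a site only when
every centimetre in it is covered by a horizon with usable SOC and bulk
density; sites therefore drop out of deeper increments, and the
contributing `n` shrinks with depth. A `prorate` option extrapolates
partial coverage instead but is off by default because it biases deep
increments downward.

Units: 100 g m⁻² = 1 tC ha⁻¹; 1 tC = 10⁻⁹ PgC, so 10⁶ ha at 1 tC ha⁻¹
holds 10⁻³ PgC.

## Quality control

Laboratory data are missing for thin (<8 cm, unsampled) horizons and for
bulk densities that failed collection or assurance. Rules
(`qc.impute_missing_carbon`, `qc.screen_bulk_density`):

* top horizon missing SOC → copy the concentration of the nearest lower
  horizon with data;
* interior missing SOC → mean of the nearest horizons with data above
  and below (runs of missing horizons share the same donors);
* bottom horizon missing SOC → copy from above (mirrors the top rule;
  `fill_bottom=False` disables it);
* a site with no SOC anywhere is unusable and excluded with a log entry;
* measured bulk density > 2.0 g cm⁻³ (the measurable ceiling) →
  replaced by the modelled value;
* measured value differing from the modelled value by more than 40% of
  the *modelled* value (the denominator is a package choice, exposed as
  `discrepancy_fraction`) → replaced;
* missing bulk density → modelled value.

Both operations are idempotent and never alter valid measurements
besides the stated replacements. Dispositions are tallied per site in a
`QCReport` (JSON-serializable).

## Bulk-density model

`bdmodel.fit_bd_model` fits stagewise boosted shallow regression trees
(squared-error loss, shrinkage, row subsampling) predicting bulk density
from ten covariates: SOC %, reporting group, EC, CEC, horizon mid-depth,
clay %, silt %, HGM class, sand %, and 1-based horizon order. The
backend is scikit-learn's `GradientBoostingRegressor`; the module
contract (loss, shrinkage, bag fraction, seeded determinism, importance
normalization) is what is tested, not the backend. Defaults: 3,000
trees, shrinkage 0.01, depth 5, bag fraction 0.5, 70/30 seeded simple
random train/holdout split; the pipeline's default config uses a lighter
500-tree / 0.05 / depth-3 spec, which reaches the same holdout skill on
the synthetic data at a fraction of the cost. Skill is holdout
R² = 1 − SSE/SST (reported 0 with a warning for a degenerate constant
response). Importance is the share of total squared-error reduction
attributable to splits on each predictor (one-hot groups summed back to
their predictor), normalized to 100. Missing numeric predictors are
filled with training medians; unseen categorical levels map to a
designated `other` level with a warning. Predictions are truncated into
(0.05, 2.0] g cm⁻³, consistent with the QC ceiling.

## Soil classification and carbon type

`classify.classify_soil` applies three histosol-style field rules:
organic if (a) no mineral horizon occurs above 40 cm and the profile is
described at least that deep; or (b) organic thickness within the top
80 cm is ≥ 40 cm; or (c) with an impenetrable layer above 40 cm, organic
material is ≥ 2/3 of described thickness and mineral material < 10 cm.
Boundary readings: "at least 40" is ≥, "<10 cm" is strict; rule (a)
tolerates no mineral cap (a thin mineral cap can still classify organic
via rule (b)). The decision is invariant to subdividing horizons.
Tidal saline sites carry blue carbon, freshwater inland sites teal.

## Disturbance screening

Sites carry ten non-negative stressor indices (five proximity-weighted
buffer counts, their summary, two in-site hydrologic counts, a soil
heavy-metal exceedance count, alien-plant relative cover). Screening is
per reporting group: least if at or below all ten least-thresholds,
most if above any most-threshold, else intermediate — monotone by
construction in every index. Because "most disturbed" is relative,
`calibrate_most_thresholds` places the most-thresholds at a common
per-group quantile of each index found by bisection so the realized
most fraction is as close as possible to a target (default 0.25,
aiming at a 20–30% band); the least-thresholds are calibrated the same
way against a least-target (default 0.25), because requiring a fixed
per-index quantile simultaneously on ten measures compounds to a
near-empty least class. Groups with fewer than 20 screened sites fall
back to pooled all-site thresholds (the analogue of relaxed thresholds
for sparse groups). Hand-picked (non-probability) sites join
calibration and screening but never population estimation. Ties and
degenerate (all-identical) indices make a target unattainable; the
nearest achievable fraction is used with a warning.

## Design-based estimation

Sites carry weights `w_i = unit area / π_i` in hectares. For a
subpopulation and depth range (`estimation.estimate_subpopulation`):
area `Â = Σ w_i`, mean density `Σ w_i y_i / Σ w_i` (tC ha⁻¹), total
`Σ w_i y_i` converted to PgC. Standard errors use the with-replacement
approximation `var(T̂) = n/(n−1) Σ (u_i − ū)²` over **all** sampled
sites of the subpopulation, with `u_i = w_i y_i` for contributing sites
and `u_i = 0` for sampled sites whose profile does not cover the range
— availability is part of the sampling randomness, and dropping the
zero terms understates the variance (in replicate simulations it cut
95% CI coverage to ~0.86; the zero-extended form achieves ~0.95). The
mean uses the ratio linearization `z_i = w_i(y_i − ŷ)` with the same
zero extension. This approximation replaces the spatially smoothed
local-neighbourhood variance estimators used with spatially balanced
designs (site coordinates are out of scope); point estimates are
unaffected and the SEs are typically mildly conservative for fixed-size
designs. No finite-population correction is applied.

`scale_to_target` extrapolates a total from the inference area to a
larger target frame by the area ratio under the assumption that the
unsampled area follows the same trends: the mean is unchanged and no
standard error is reported for the scaled value. The pipeline applies
one common ratio — target area over the full realized inference area —
to every depth row.

## Synthetic populations

`simulate.generate_population` builds a finite population with exact
ground truth so every stage is testable without survey data. Study
conditions (defaults): 2,000 population sites, samples of 200 plus 35
hand-picked calibration-only sites, a 25.2 Mha frame; thin-horizon rate
0.25 and bulk-density missingness 0.30 (the approximate rates reported
for the 2011 survey); SOC decays exponentially with depth from organic
(surface mean 30%, decay 0.003 cm⁻¹, organic field texture to ≥45 cm)
or mineral (8%, 0.02 cm⁻¹, optional thin organic cap) archetypes with
lognormal noise (σ = 0.25); bulk density follows
`rho_d = 1.6·exp(−0.08·SOC%) + N(0, 0.1)` truncated to (0.05, 2.0],
which reproduces the strong dominance of SOC as a bulk-density
predictor and plausible peat-to-mineral densities; 30% of profiles stop
on an impenetrable layer drawn uniformly in 35–119 cm, exercising the
shrinking deep-increment n; a latent least/intermediate/most class
(mix 0.25/0.50/0.25) scales the gamma-distributed stressor indices and
multiplies SOC at most-disturbed sites by 0.6 minus a depth-increasing
term (0.2·depth/120) — a device to create a least-vs-most density gap,
not a mechanistic claim. 1% of measured bulk densities are corrupted
above 2 g cm⁻³ to exercise the QC ceiling rule. Sampling is
randomized-order systematic PPS with inclusion probabilities
proportional to wetland-type factors (estuarine types oversampled),
giving fixed sample sizes, exact inclusion probabilities and
Horvitz-Thompson unbiasedness. All randomness flows from one master
seed through spawned child generators; outputs are identical across
runs for a fixed seed.

Ground truth (totals and means per subpopulation × depth range) is
computed from the complete pre-masking population by the same slicing
arithmetic, restricted — like the estimator — to sites whose profile
covers the range.

What the generator does **not** emulate: spatial structure and
spatially balanced (GRTS) selection, landowner-denial missingness
beyond uniform rates, correlated index structure within the stressor
vector, laboratory measurement error models, and real distributions of
horizon thickness or texture. Passing tests therefore demonstrate the
correctness of the accounting, screening and estimation machinery under
a faithful-but-idealized data-generating process, not the field
accuracy of any published number.

## Numerical choices and problem sizes

* Bisection for threshold calibration: 60 iterations on the quantile
  level; nearest-achievable fraction under ties.
* Contiguity tolerance for horizon stacks: 1e-9 cm; slice availability
  requires coverage within 1e-9 cm of a full centimetre.
* CSV floats are written at full precision and read with pandas'
  `round_trip` parser, so write-then-read is exact.
* Replicate-based checks use 500 samples of n = 200 from the
  2,000-site default population (seconds of runtime); unit-test
  variants use 200 replicates from a 400-site population. These sizes
  put Monte-Carlo error well below the 3-SE and coverage bands being
  asserted.

## Known limitations

* Standard errors ignore the spatial balance of real survey designs
  (no local-neighbourhood variance, no joint-inclusion corrections).
* The least/most threshold values themselves are calibration outputs,
  not published constants; only the screening structure is fixed.
* Organic/mineral classification relies on field texture flags; no
  taxonomic keying beyond the three rules.
* Scaled (target-population) totals inherit the untestable assumption
  that unsampled area behaves like sampled area, and carry no SEs.
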