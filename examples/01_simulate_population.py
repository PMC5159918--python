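"""Generate a synthetic wetland population and draw a probability sample.

The generator builds a finite population of wetland sites with soil
profiles (exponential SOC depth-decay, a bulk-density-SOC relation,
thin unsampled horizons, missing bulk density) and exact ground-truth
stocks, then draws an unequal-probability survey sample with
inverse-probability weights in hectares.
"""

from wetcarbon import SimulationConfig, generate_population, sample_survey

cfg = SimulationConfig(seed=1)
population, profiles, truth = generate_population(cfg)
sampled, handpicked = sample_survey(population, cfg)

print(f"population sites: {len(population)}, "
      f"probability sample: {len(sampled)}, "
      f"hand-picked (calibration-only): {len(handpicked)}")
print(f"horizons in population: {sum(len(p) for p in profiles.values())}")

total = truth.true_total_PgC[("national", "0-120")]
mean = truth.true_mean_tC_ha[("national", "0-120")]
print(f"true national stock 0-120 cm: {total:.2f} PgC "
      f"(mean density {mean:.0f} tC/ha over sites described to 120 cm)")
blue = truth.true_total_PgC[("carbon:blue", "0-120")]
print(f"true tidal-saline (blue) share: {100 * blue / total:.1f}% of the stock")

w = sum(s.weight_ha for s in sampled)
print(f"weighted sample represents {w / 1e6:.1f} Mha "
      f"(frame is {cfg.frame_area_ha / 1e6:.1f} Mha)")
# The weighted area fluctuates around the frame area across draws; the
# Horvitz-Thompson estimator built on these weights is design-unbiased.
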