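"""Summary ratios recomputed from the published 2011 NWCA stock tables.

The published national estimates (stocks by depth increment and
subpopulation, screened-site counts, deep-layer bulk-density tallies)
are inputs here; the package's aggregation operations recompute the
derived percentages and differences usually quoted from them.
"""

from wetcarbon import published
from wetcarbon.disturbance import gradient_summary
from wetcarbon.estimation import area_shares, depth_shares

target = published.published_estimates("target")
inference = published.published_estimates("inference")

shares = depth_shares(target["national"])
deep = sum(v for (lo, _), v in shares.items() if lo >= 30)
print(f"share of the target-population stock below 30 cm: {deep:.0f}%")

teal = depth_shares(inference["teal"])
print(f"teal depth shares: {teal[(0, 30)]:.1f}% in 0-30 cm, "
      f"{teal[(90, 120)]:.1f}% in 90-120 cm")

a = area_shares([inference["blue"][0], inference["teal"][0]])
print(f"area split: {a['teal']:.0f}% inland, {a['blue']:.0f}% tidal saline")

gap = published.DISTURBANCE_MEAN_TC_HA["least"] \
    - published.DISTURBANCE_MEAN_TC_HA["most"]
print(f"least-minus-most mean density difference: {gap:.0f} tC/ha")

labels = [c for c, n in published.SCREENED_COUNTS.items() for _ in range(n)]
s = gradient_summary(labels)
print(f"disturbance gradient: {s['percent']['least']}% least / "
      f"{s['percent']['intermediate']}% intermediate / "
      f"{s['percent']['most']}% most of {s['total']} screened sites")

share = 100 * published.DEEP_LAYERS_BD_MODELLED / published.DEEP_LAYERS_DESCRIBED
print(f"bulk density modelled for {share:.0f}% of layers at 75 cm or deeper")
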