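"""Organic vs mineral soil classification and blue vs teal carbon.

A wetland is organic-soil dominated if (a) every horizon down to at
least 40 cm is organic, or (b) at least 40 cm of the top 80 cm is
organic, or (c) above a shallow impenetrable layer (<40 cm) two-thirds
of the soil is organic with under 10 cm of mineral material.  Tidal
saline sites hold blue carbon; freshwater inland sites hold teal carbon.
"""

from wetcarbon import SoilHorizon, carbon_type, classify_soil
from wetcarbon.model import REGION_BY_GROUP, SiteRecord


def prof(layers, site="demo"):
    out, top = [], 0.0
    for k, (t, organic) in enumerate(layers):
        out.append(SoilHorizon(site, k + 1, top, top + t,
                               organic_flag=organic, soc_pct=5, bd_g_cm3=1))
        top += t
    return out


cases = [
    ("peat to 45 cm over mineral", prof([(45, True), (75, False)]), None),
    ("mineral throughout", prof([(120, False)]), None),
    ("buried organic layers, 45 organic cm in top 80",
     prof([(20, True), (30, False), (25, True), (45, False)]), None),
    ("shallow profile on rock at 30 cm, mostly peat",
     prof([(21, True), (9, False)]), 30.0),
]
for label, p, impenetrable in cases:
    print(f"{label}: {classify_soil(p, impenetrable)}")

for group in ("ALL-EH", "EMU-PRLH"):
    site = SiteRecord(f"x-{group}", group, REGION_BY_GROUP[group],
                      "EH" if group == "ALL-EH" else "PRL-EM", "Depression",
                      group.startswith("ALL-"), 1e4)
    print(f"{group}: {carbon_type(site)} carbon")
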