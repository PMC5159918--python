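"""Carbon density of a soil profile, sliced to 1-cm increments.

A layer's carbon density is rho_c = 10,000 * d_l * rho_d * C (g/m^2)
with thickness d_l in cm, bulk density rho_d in g/cm^3 and SOC fraction
C.  Slicing a profile into 1-cm increments lets stocks be summed over
any depth range; 100 g/m^2 is 1 tC/ha.
"""

from wetcarbon import (
    SoilHorizon,
    depth_range_density,
    horizon_carbon_density,
    slice_profile,
)

# a peaty surface horizon over mineral subsoil, described to 100 cm
profile = [
    SoilHorizon("demo", 1, 0, 35, organic_flag=True, soc_pct=28.0,
                bd_g_cm3=0.22),
    SoilHorizon("demo", 2, 35, 70, soc_pct=6.0, bd_g_cm3=0.95),
    SoilHorizon("demo", 3, 70, 100, soc_pct=2.0, bd_g_cm3=1.35),
]

for h in profile:
    rho_c = horizon_carbon_density(h.thickness_cm, h.bd_g_cm3, h.soc_pct)
    print(f"horizon {h.horizon_order} ({h.top_depth_cm:.0f}-"
          f"{h.bottom_depth_cm:.0f} cm): {rho_c:,.0f} g/m^2 "
          f"= {rho_c / 100:.0f} tC/ha")

sliced = slice_profile(profile)
print(f"described (available) depth: {sliced.described_bottom_cm()} cm")
for lo, hi in [(0, 30), (30, 60), (60, 90), (90, 120), (0, 100)]:
    d = depth_range_density(sliced, lo, hi)
    label = f"{d:.0f} tC/ha" if d is not None else \
        "unavailable (profile does not cover the range)"
    print(f"  {lo:>3}-{hi:<3} cm: {label}")
# The 90-120 range is unavailable: this site drops out of deep-increment
# population estimates, which is how n shrinks with depth in reporting.
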