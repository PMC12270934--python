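"""Forward ice curve, hydration-number inversion and melting point.

A 15 % glucose solution with effective hydration number h = 10.5 is pushed
through the forward model on a temperature grid; one point is inverted
back to h (exact closed form), and the melting point (where the raw ice
curve crosses zero) is located by root search.
"""

import numpy as np

from icecurve import (
    SolutionComposition,
    hydration_number_from_point,
    ice_curve,
    load_registry,
    melting_point,
    serum_concentration,
    unfrozen_water_pct,
)

registry = load_registry()
comp = SolutionComposition.single(registry.get("glucose"), 15.0)
h = 10.5  # mol bound water per mol glucose

print("T °C    ice %   serum glucose %   unfrozen water %")
for p in ice_curve(comp, h, np.arange(-18.0, -7.0, 2.0)):
    serum = serum_concentration(comp, p.ice_content_pct)["glucose"]
    ufw = unfrozen_water_pct(comp, p.ice_content_pct)
    print(f"{p.temperature:5.0f}   {p.ice_content_pct:5.1f}   {serum:15.1f}   {ufw:16.1f}")

ice_at_18 = ice_curve(comp, h, [-18.0])[0].ice_content_pct
h_back = hydration_number_from_point(comp, -18.0, ice_at_18)
print(f"\ninverting the −18 °C point ({ice_at_18:.1f} % ice) returns h = {h_back:.3f}")
print(f"melting point of the premix at h = {h}: {melting_point(comp, h):.2f} °C")
print(f"melting point at h = 0 (no bound water): {melting_point(comp, 0.0):.2f} °C")
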