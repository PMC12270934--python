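# icecurve

Freezing thermodynamics of aqueous anti-freeze-agent solutions: ice curves,
effective hydration numbers, serum-phase freeze concentration, and the
physical characterisation (melting behaviour, hardness) of frozen-dessert
model systems.

`icecurve` is for food physical chemists and formulation scientists who
need to compare cryoprotectants — sugars, polyols, alcohols, salts — by how
much ice they allow at a given sub-zero temperature, how concentrated the
unfrozen serum phase becomes, and how the frozen product melts.

## The model

A premix of water and solutes partially freezes until the unfrozen serum
reaches the solute mole fraction demanded by the freezing equilibrium at
temperature *T* (kelvin):

```
x_s(T) = 1 − exp(a − b/T),     b = ΔH_fus/R = 722.8 K,   a = b/T_water = 2.646
```

Each solute additionally binds an average of *h* water molecules per
molecule (its **effective hydration number**), which are unavailable for
freezing. The moles of ice are therefore

```
n_ice(T) = n_water − (1/x_s − 1)·n_s − Σ n_s·h_s
```

and the **ice curve** is `%ice(T) = 100·MW_water·n_ice/(m_water+m_solute)`,
a percentage of total sample mass. The expression inverts in closed form:
one measured ice content at one temperature yields *h* exactly, which is
how effective hydration surfaces *h(c, T)* are tabulated from calorimetric
(DSC) data — melting enthalpy ÷ 334 J/g gives the ice fraction. Around the
core model the package provides:

- ideal colligative freezing points, `ΔT_f = K_k·i·m` (K_k = 1.86 K·kg/mol),
  and least-squares effective dissociation degrees for ionic solutes;
- serum-phase freeze concentration, `%solute = 100·m_s/(m_total − m_ice)`,
  and unfrozen-water content;
- melting points by bracketed root search of the raw ice curve;
- DSC endotherm integration (linear baseline, trapezoidal rule);
- melting-curve parameter extraction (total melting time, lag time, melting
  rate, onset temperature, temperature-increase rate) and penetration-test
  hardness;
- seeded synthetic generators for all three measurement types, so every
  stage is testable against a known ground truth.

## Worked example

```python
import numpy as np
from icecurve import (SolutionComposition, load_registry, ice_curve,
                      hydration_number_from_point, melting_point)

registry = load_registry()                      # glucose, sucrose, ... NaCl
comp = SolutionComposition.single(registry.get("glucose"), 15.0)  # 15 % w/w

for p in ice_curve(comp, 10.5, np.arange(-18.0, -7.0, 2.0)):
    print(f"{p.temperature:5.0f} °C  {p.ice_content_pct:5.1f} % ice")
print(melting_point(comp, 10.5))
```

prints

```
  -18 °C   61.9 % ice
  -16 °C   60.8 % ice
  -14 °C   59.5 % ice
  -12 °C   57.6 % ice
  -10 °C   55.0 % ice
   -8 °C   51.2 % ice
-2.2035072994232178
```

A 15 % glucose solution whose molecules each bind 10.5 water molecules is
61.9 % ice at −18 °C; warming melts ice monotonically until the curve
crosses zero at −2.2 °C, the premix melting point. Inverting the −18 °C
point returns h = 10.500 exactly. The `examples/` directory holds one short
script per capability (freezing points, ice curves, hydration-surface
fitting, DSC processing, melting/hardness analysis); each prints the
numbers it computes and what they mean.

A thin CLI wraps the same calls, e.g.
`icecurve freezing-point glucose 11.5` → `-1.34 °C`, and
`icecurve serum sucrose 15 --ice 70` → `sucrose: 50 %`.

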