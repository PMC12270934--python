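"""Recover an effective-hydration surface from synthetic measurements.

Generates a replicated ice-content dataset from a known h(c, T) ground
truth (plus measurement noise), fits the hydration table cell by cell, and
compares fitted to generating values — the workflow used to tabulate
effective hydration numbers from calorimetric ice contents.
"""

import numpy as np

from icecurve import (
    GeneratorConfig,
    HydrationAssignment,
    HydrationTable,
    SolutionComposition,
    fit_hydration_table,
    generate_ice_dataset,
    load_registry,
    predict_ice_curve,
)

registry = load_registry()
temps = [-18.0, -16.0, -14.0, -12.0, -10.0, -8.0]
truth = {15.0: 10.5, 20.0: 4.9, 25.0: 5.0}  # h at −18 °C per concentration
surface = HydrationTable(
    [HydrationAssignment("glucose", c, t, h) for c, h in truth.items() for t in temps]
)

data = generate_ice_dataset(
    registry, surface, ["glucose"], list(truth), temps,
    GeneratorConfig(seed=42, noise_sd_ice=0.5, replicates=3),
)
print(f"dataset: {len(data.records)} replicate measurements "
      f"({len(truth)} concentrations × {len(temps)} temperatures × 3 replicates)")

table = fit_hydration_table(data, registry)  # mean-then-invert per cell
print("\nconc %   T °C   fitted h   true h")
for e in table.entries:
    if e.temperature == -18.0:
        print(f"{e.concentration_pct:5.0f}   {e.temperature:5.0f}   {e.h:8.2f}   {truth[e.concentration_pct]:6.1f}")

comp = SolutionComposition.single(registry.get("glucose"), 20.0)
predicted = predict_ice_curve(comp, table, temps)
errors = [
    abs(p.ice_content_pct - q)
    for p, q in zip(
        predicted,
        [
            np.mean(
                data.records.query("concentration_pct == 20 and temperature_c == @t")["ice_pct"]
            )
            for t in temps
        ],
    )
]
print("\npredicted ice curve reproduces the replicate means at 20 % exactly "
      f"(max |Δ| = {max(errors):.2g} % ice): the fit is the closed-form inverse "
      "of the prediction")
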