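"""From a DSC heating ramp to an ice content.

Generates a synthetic final heating ramp whose melting endotherm carries a
known ice fraction, integrates the baseline-corrected peak over time, and
converts the enthalpy to an ice content via the 334 J/g pure-ice
normalisation.
"""

from icecurve import (
    GeneratorConfig,
    generate_dsc_trace,
    ice_content_from_enthalpy,
    integrate_endotherm,
)

truth = 62.0  # % ice ground truth encoded in the peak area
trace = generate_dsc_trace(
    truth, peak_center_c=-2.0, peak_width_c=1.5, drift_slope=2e-6,
    cfg=GeneratorConfig(seed=5),
)
print(f"trace: {trace.time_s.size} samples, "
      f"{trace.temperature_c.min():.0f} → {trace.temperature_c.max():.0f} °C at 1 °C/min")

enthalpy = integrate_endotherm(trace, window=(-12.0, 8.0))
ice = ice_content_from_enthalpy(enthalpy)
print(f"baseline-corrected endotherm area: {enthalpy:.1f} J/g of sample")
print(f"ice content = 100 · {enthalpy:.1f} / 334 = {ice:.1f} %  (truth {truth} %)")
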