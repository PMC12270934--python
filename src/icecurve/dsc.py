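"""DSC endotherm quantification.

A partially frozen sample heated through its melting range absorbs the
enthalpy of fusion of whatever ice it contains.  Integrating the melting
endotherm of the final heating ramp (heat flow vs. time, minus a linear
baseline) gives a specific enthalpy in J per g of sample; dividing by the
enthalpy of pure ice (334 J/g) converts it to an ice content in % of
sample mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, ThermoConstants

__all__ = ["DSCTrace", "EnthalpyMeasurement", "integrate_endotherm", "ice_content_from_enthalpy"]


@dataclass
class DSCTrace:
    """One heating-ramp heat-flow trace.

    ``heat_flow`` is in J·s⁻¹ per g of sample.  ``endotherm_positive``
    records the instrument sign convention; traces are normalised to
    endotherm-positive on construction.
    """

    time_s: np.ndarray
    temperature_c: np.ndarray
    heat_flow: np.ndarray  # J/s/g of sample, endotherm-positive after init
    sample_mass_mg: float = 11.0
    annealing_temperature_c: float | None = None
    endotherm_positive: bool = True

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.time_s.size < 10:
            raise ValueError("trace must have at least 10 samples")
        if not (self.time_s.shape == self.temperature_c.shape == self.heat_flow.shape):
            raise ValueError("time, temperature and heat flow must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.endotherm_positive:
            self.heat_flow = -self.heat_flow
            self.endotherm_positive = True


@dataclass(frozen=True)
class EnthalpyMeasurement:
    """Melting enthalpy of one replicate, J per g of sample."""

    solute: str
    concentration_pct: float
    annealing_temperature_c: float
    replicate: int
    specific_enthalpy: float

    def __post_init__(self) -> None:
        if self.specific_enthalpy < 0:
            raise ValueError("specific enthalpy must be ≥ 0")


def integrate_endotherm(trace: DSCTrace, window: tuple[float, float]) -> float:
    """Baseline-corrected endotherm area over a temperature window, J/g.

    The window ``(T_start, T_end)`` selects the integration range on the
    (monotone) heating ramp; a straight baseline joins the heat flow at the
    two window endpoints and the excess above it is integrated over *time*
    with the trapezoidal rule.  A baseline crossing the signal more than
    twice triggers a warning (peak probably clipped or window misplaced).
    """
    t_start, t_end = sorted(window)
    temp = trace.temperature_c
    if t_start < temp.min() - 1e-9 or t_end > temp.max() + 1e-9:
        raise ValueError(
            f"window ({t_start}, {t_end}) °C outside trace range "
            f"({temp.min():.2f}, {temp.max():.2f}) °C"
        )
    mask = (temp >= t_start) & (temp <= t_end)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 samples inside the integration window")
    t = trace.time_s[mask]
    hf = trace.heat_flow[mask]
    # straight baseline through the window endpoints, parameterised by time
    baseline = hf[0] + (hf[-1] - hf[0]) * (t - t[0]) / (t[-1] - t[0])
    excess = hf - baseline
    # count baseline crossings of the *significant* part of the signal so
    # instrument noise around the baseline does not trip the warning
    scale = np.abs(excess).max()
    if scale > 1e-9 * max(np.abs(hf).max(), 1e-30):
        significant = excess[np.abs(excess) > 0.05 * scale]
        crossings = np.count_nonzero(np.diff(np.sign(significant)) != 0)
    else:  # numerically flat after baseline removal
        crossings = 0
    if crossings > 2:
        warnings.warn(
            f"baseline crosses the signal {crossings} times; check the integration window",
            stacklevel=2,
        )
    return float(np.trapezoid(excess, t))


def ice_content_from_enthalpy(
    measurement: "EnthalpyMeasurement | float",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert a melting enthalpy (J/g of sample) to ice content, % of sample.

    ``100 · ΔH / 334``; values above 100 % (enthalpy exceeding pure ice)
    are capped at 100 with a warning.
    """
    dh = (
        measurement.specific_enthalpy
        if isinstance(measurement, EnthalpyMeasurement)
        else float(measurement)
    )
    if dh < 0:
        raise ValueError("specific enthalpy must be ≥ 0")
    pct = 100.0 * dh / constants.latent_heat_ice
    if pct > 100.0:
        warnings.warn(
            f"enthalpy {dh:.1f} J/g exceeds that of pure ice; capping ice content at 100 %",
            stacklevel=2,
        )
        return 100.0
    return pct
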