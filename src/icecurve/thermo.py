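"""Freezing equilibrium of aqueous anti-freeze-agent solutions.

The model combines three ingredients:

1. **Colligative freezing-point depression.**  For a dilute ideal solution
   the depression is ``ΔT_f = K_k · i · m`` with ``K_k`` the cryoscopic
   constant of water (1.86 K·kg·mol⁻¹), ``m`` the molality and ``i`` the
   degree of dissociation.

2. **Equilibrium solute mole fraction.**  At sub-zero temperature ``T`` (K)
   a partially frozen solution equilibrates when the serum-phase solute mole
   fraction reaches ``x_s(T) = 1 − exp(a − b/T)``, with ``b = ΔH_fus/R =
   722.8 K`` and ``a = b/T_water = 2.646``.  The colder the sample, the more
   concentrated the unfrozen serum must be, hence the more ice exists.

3. **Bound (hydration) water.**  Each solute molecule binds on average ``h``
   water molecules (its effective hydration number); bound water is
   unavailable for freezing.  The moles of ice at temperature ``T`` are

       n_ice = n_water − (1/x_s − 1)·n_s − Σ n_s·h_s ,

   i.e. total water minus the free serum water required by equilibrium minus
   the hydration shell.  Expressed as a percentage of total sample mass this
   is the *ice curve*; solved for ``h`` at a measured ice content it yields
   the *effective hydration number*; solved for the temperature where
   ``n_ice = 0`` it yields the melting point of the premix.

All public temperatures are in °C; the model converts to kelvin internally.
Ice contents are percentages of **total sample mass** (water + solutes), the
basis on which serum freeze-concentration round-trips exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .solutes import SoluteSpec, SolutionComposition

__all__ = [
    "IceCurvePoint",
    "HydrationAssignment",
    "freezing_point_colligative",
    "equilibrium_solute_mole_fraction",
    "ice_content",
    "ice_curve",
    "serum_concentration",
    "unfrozen_water_pct",
    "melting_point",
    "hydration_number_from_point",
    "fit_dissociation_degree",
]

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class IceCurvePoint:
    """Ice content at one temperature.

    ``valid`` is False when the raw model value was negative (temperature at
    or above the melting point) and the reported content was clamped to 0.
    """

    temperature: float  # °C
    ice_content_pct: float  # % of total sample mass
    valid: bool = True


@dataclass(frozen=True)
class HydrationAssignment:
    """Effective hydration number of one solute at one (c, T) cell.

    ``h`` is in mol bound water per mol solute.  ``flagged`` marks a
    physically inconsistent (negative) fitted value that is reported rather
    than clamped.
    """

    solute: str
    concentration_pct: float
    temperature: float  # °C
    h: float
    flagged: bool = False


def _normalize_h(
    comp: SolutionComposition, h_by_solute: "Mapping[str, float] | float"
) -> dict[str, float]:
    if isinstance(h_by_solute, (int, float)):
        return {spec.name: float(h_by_solute) for spec, _ in comp.solutes}
    out = {}
    for spec, _ in comp.solutes:
        try:
            out[spec.name] = float(h_by_solute[spec.name])
        except KeyError:
            raise KeyError(f"no hydration number provided for solute {spec.name!r}") from None
    for name, h in out.items():
        if h < 0:
            raise ValueError(f"hydration number for {name!r} must be ≥ 0, got {h}")
    return out


def freezing_point_colligative(
    comp: SolutionComposition, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Ideal colligative freezing point of the premix, °C.

    ``T_f = −K_k · Σ_s i_s · m_s / M_s / m_water[kg]`` — additive over
    solutes, 0 for pure water, always ≤ 0.
    """
    if comp.water_mass <= 0:
        raise ValueError("composition has no water")
    if not comp.solutes:
        return 0.0
    water_kg = comp.water_mass / 1000.0
    depression = 0.0
    for spec, pct in comp.solutes:
        mass = pct * comp.basis_mass / 100.0
        molality = mass / spec.molecular_weight / water_kg
        depression += constants.cryoscopic_constant * spec.dissociation_degree * molality
    return -depression


def equilibrium_solute_mole_fraction(
    temperature_c: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Equilibrium serum-phase solute mole fraction ``x_s = 1 − exp(a − b/T)``.

    ``temperature_c`` in °C, converted to kelvin internally.  The value is
    ≤ 0 at and above the temperature where ``a = b/T``; callers interpret a
    non-positive value as "no ice can coexist".
    """
    t_k = temperature_c + KELVIN_OFFSET
    if t_k <= 0:
        raise ValueError(f"non-physical absolute temperature {t_k} K")
    return 1.0 - math.exp(constants.a - constants.b / t_k)


def _raw_ice_moles(
    comp: SolutionComposition,
    h: Mapping[str, float],
    temperature_c: float,
    constants: ThermoConstants,
) -> float:
    """Unclamped moles of ice; negative above the melting point."""
    x_s = equilibrium_solute_mole_fraction(temperature_c, constants)
    if x_s <= 0:
        return -math.inf
    n_water = comp.water_mass / constants.molar_mass_water
    n_s_total = comp.total_solute_moles
    bound = sum(n * h[name] for name, n in comp.solute_moles().items())
    return n_water - (1.0 / x_s - 1.0) * n_s_total - bound


def ice_content(
    comp: SolutionComposition,
    h_by_solute: "Mapping[str, float] | float",
    temperature_c: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> IceCurvePoint:
    """Ice content of the sample at ``temperature_c``, % of total sample mass.

    Negative raw values (temperature at/above the melting point, or all
    water bound by hydration) are clamped to 0 and flagged ``valid=False``.
    """
    h = _normalize_h(comp, h_by_solute)
    raw = _raw_ice_moles(comp, h, temperature_c, constants)
    pct = 100.0 * constants.molar_mass_water * raw / comp.basis_mass
    if pct < 0 or not math.isfinite(pct):
        return IceCurvePoint(temperature_c, 0.0, valid=False)
    return IceCurvePoint(temperature_c, pct, valid=True)


def ice_curve(
    comp: SolutionComposition,
    h_by_solute: "Mapping[str, float] | float",
    temperatures_c: "Sequence[float] | np.ndarray",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[IceCurvePoint]:
    """Evaluate :func:`ice_content` on a temperature grid."""
    return [ice_content(comp, h_by_solute, float(t), constants) for t in temperatures_c]


def serum_concentration(
    comp: SolutionComposition, ice_content_pct: float
) -> dict[str, float]:
    """Freeze-concentrated serum-phase solute concentrations, % w/w.

    As ice forms, solutes concentrate in the unfrozen serum; each solute's
    serum concentration is ``100·m_s / (basis − m_ice)``.  ``ice_content_pct``
    is the ice content as % of total sample mass.
    """
    if ice_content_pct < 0:
        raise ValueError("ice content must be ≥ 0")
    m_ice = ice_content_pct * comp.basis_mass / 100.0
    denom = comp.basis_mass - m_ice
    if denom <= 0 or m_ice > comp.water_mass:
        raise ValueError(
            f"ice content {ice_content_pct} % exceeds the available water "
            f"({100 * comp.water_mass / comp.basis_mass:.1f} % of sample)"
        )
    return {
        spec.name: 100.0 * (pct * comp.basis_mass / 100.0) / denom
        for spec, pct in comp.solutes
    }


def unfrozen_water_pct(comp: SolutionComposition, ice_content_pct: float) -> float:
    """Unfrozen-water content, % of sample: moisture minus ice."""
    moisture = 100.0 * comp.water_mass / comp.basis_mass
    ufw = moisture - ice_content_pct
    if ufw < -1e-9:
        raise ValueError(
            f"ice content {ice_content_pct} % exceeds moisture content {moisture:.2f} %"
        )
    return max(ufw, 0.0)


def melting_point(
    comp: SolutionComposition,
    h_by_solute: "Mapping[str, float] | float",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    bracket: tuple[float, float] = (-40.0, -1e-9),
    xtol: float = 1e-6,
) -> float:
    """Melting point of the premix: where the ice curve crosses zero, °C.

    Found by bracketed root search of the raw (unclamped) ice moles on
    ``bracket``; pure water returns 0.  Raises if the model predicts ice at
    the warm end of the bracket is impossible to melt within it or if all
    water is bound (no sign change).
    """
    if not comp.solutes:
        return 0.0
    h = _normalize_h(comp, h_by_solute)

    def f(t: float) -> float:
        return _raw_ice_moles(comp, h, t, constants)

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0:
        raise ValueError(
            f"no melting point in [{lo}, {hi}] °C: no ice predicted even at {lo} °C "
            "(all water may be bound)"
        )
    if f_hi > 0:
        raise ValueError(f"no melting point in [{lo}, {hi}] °C: ice persists at {hi} °C")
    return float(brentq(f, lo, hi, xtol=xtol))


def hydration_number_from_point(
    comp: SolutionComposition,
    temperature_c: float,
    ice_content_pct: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Effective hydration number from one measured ice content.

    Closed-form inversion of the ice-curve expression for a single-solute
    composition:

        h = (n_water − n_ice − (1/x_s − 1)·n_s) / n_s

    with ``n_ice = m_ice / MW_water``.  Exact inverse of :func:`ice_content`
    (round-trip error below 1e-9 %).  A negative result marks a physically
    inconsistent measurement; it is returned as-is with a warning, never
    silently clamped.
    """
    if len(comp.solutes) != 1:
        raise ValueError("hydration inversion is defined for single-solute compositions")
    x_s = equilibrium_solute_mole_fraction(temperature_c, constants)
    if x_s <= 0:
        raise ValueError(
            f"{temperature_c} °C is at or above the equilibrium limit; no ice can coexist"
        )
    n_water = comp.water_mass / constants.molar_mass_water
    n_ice = (ice_content_pct * comp.basis_mass / 100.0) / constants.molar_mass_water
    n_s = comp.total_solute_moles
    h = (n_water - n_ice - (1.0 / x_s - 1.0) * n_s) / n_s
    if h < 0:
        warnings.warn(
            f"negative hydration number ({h:.4g}) at {temperature_c} °C, "
            f"ice {ice_content_pct} %: measurement inconsistent with the model",
            stacklevel=2,
        )
    return h


def fit_dissociation_degree(
    solute: SoluteSpec,
    observations: "Iterable[tuple[float, float]]",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Effective degree of dissociation from (concentration %, freezing point °C) pairs.

    Least squares of ``ΔT_obs = K_k · i · molality`` through the origin:
    ``i = Σ x·ΔT / Σ x²`` with ``x = K_k·molality``.  Useful for ionic
    solutes whose measured freezing points deviate from the ideal ``i``
    (ion pairing at freezing temperatures); the fitted value is a
    calibration, never substituted silently.
    """
    xs, ys = [], []
    for conc_pct, tf_c in observations:
        water_kg = (100.0 - conc_pct) / 1000.0
        if water_kg <= 0:
            raise ValueError(f"concentration {conc_pct} % leaves no water")
        molality = conc_pct / solute.molecular_weight / water_kg
        xs.append(constants.cryoscopic_constant * molality)
        ys.append(-tf_c)  # depression is positive
    if not xs:
        raise ValueError("at least one observation required")
    sxx = sum(x * x for x in xs)
    if sxx == 0:
        raise ValueError("all molalities are zero; i is unidentifiable")
    return sum(x * y for x, y in zip(xs, ys)) / sxx
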