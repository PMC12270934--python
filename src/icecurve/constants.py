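"""Physical constants of the ice-curve model.

The model treats an aqueous solution of one or more anti-freeze agents
(sugars, polyols, alcohols, salts) in equilibrium with ice.  Two constants
control the equilibrium solute mole fraction ``x_s = 1 - exp(a - b/T)``:
``b = ΔH_fus / R`` (in kelvin) and ``a = b / T_water`` (dimensionless).
The remaining constants are the cryoscopic constant of water, the latent
heat of fusion of ice used to convert melting enthalpies to ice fractions,
and the molar masses needed for mole bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ThermoConstants", "DEFAULT_CONSTANTS", "PRINTED_A_CONSTANTS"]

#: Rounded value of ``a`` as conventionally printed at 3 decimals.
PRINTED_A = 2.646


@dataclass(frozen=True)
class ThermoConstants:
    """Constants of the freezing-equilibrium model.

    Parameters
    ----------
    cryoscopic_constant :
        Magnitude of the cryoscopic constant of water, K·kg·mol⁻¹.
    b :
        ΔH_fus/R in kelvin; sets the temperature scale of the
        equilibrium mole-fraction curve.
    t_water :
        Freezing point of pure water, K.
    latent_heat_ice :
        Enthalpy of fusion of pure ice, J·g⁻¹ (DSC normalisation).
    molar_mass_water :
        g·mol⁻¹.
    gas_constant :
        J·K⁻¹·mol⁻¹.
    use_printed_a :
        When True, ``a`` is the rounded 2.646 instead of the exact
        ``b / t_water`` (difference in ``x_s`` below 0.02 %); provided so
        published tables computed with the rounded constant can be
        reproduced bit-for-bit.
    """

    cryoscopic_constant: float = 1.86
    b: float = 722.8
    t_water: float = 273.15
    latent_heat_ice: float = 334.0
    molar_mass_water: float = 18.015
    gas_constant: float = 8.314
    use_printed_a: bool = False

    def __post_init__(self) -> None:
        for field in (
            "cryoscopic_constant",
            "b",
            "t_water",
            "latent_heat_ice",
            "molar_mass_water",
            "gas_constant",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")
        # the rounded published value must stay consistent with b/T_water
        if abs(PRINTED_A - self.b / self.t_water) > 5e-4:
            raise ValueError("a (b/t_water) inconsistent with the printed 2.646")

    @property
    def a(self) -> float:
        """Dimensionless ``a = b / T_water`` (or the rounded 2.646)."""
        if self.use_printed_a:
            return PRINTED_A
        return self.b / self.t_water


DEFAULT_CONSTANTS = ThermoConstants()
PRINTED_A_CONSTANTS = ThermoConstants(use_printed_a=True)
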