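"""Seeded generators emulating the study-style measurements.

Three instruments are emulated so that every pipeline stage can be tested
end to end without raw data:

* replicated ice-content tables per (solute, concentration, annealing
  temperature), built from a ground-truth hydration surface through the
  forward ice-curve model plus Gaussian measurement noise;
* melting curves with the characteristic lag / fast-linear-phase / plateau
  drip-mass shape and a core-temperature trace that saturates smoothly to
  the near-0 °C melting plateau;
* DSC heating ramps carrying a Gaussian melting endotherm whose analytic
  area encodes the ground-truth ice content (area = %ice · 334 / 100 J/g)
  on a drifting linear baseline.

All randomness flows from ``GeneratorConfig.seed``; identical configs give
byte-identical outputs.  Noise is additive Gaussian throughout — the
simplest model consistent with replicate scatter reported as ± standard
deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .dsc import DSCTrace
from .hydration import HydrationTable, IceContentDataset
from .props import MeltingCurve, MeltingParameters
from .solutes import SoluteRegistry, SolutionComposition
from .thermo import ice_content

__all__ = [
    "GeneratorConfig",
    "generate_ice_dataset",
    "generate_melting_curve",
    "melting_curve_truth",
    "generate_dsc_trace",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise levels and sampling settings shared by the generators.

    Defaults mirror the emulated protocols: triplicate measurements, 10 s
    logging cadence for melting tests, ice-content noise of 1 % absolute
    (the magnitude of typical replicate standard deviations), balance noise
    of 0.1 g, thermocouple noise of 0.1 °C, and DSC heat-flow noise of
    2·10⁻⁴ J·s⁻¹·g⁻¹ (a few µW on a ~10 mg sample).
    """

    seed: int = 0
    noise_sd_ice: float = 1.0  # % absolute
    replicates: int = 3
    sampling_interval_s: float = 10.0
    noise_sd_mass: float = 0.1  # g
    noise_sd_temp: float = 0.1  # °C
    noise_sd_heatflow: float = 2e-4  # J/s/g

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")
        for f in ("noise_sd_ice", "noise_sd_mass", "noise_sd_temp", "noise_sd_heatflow"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be ≥ 0")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _h_lookup(
    h_surface: "HydrationTable | Mapping[str, float] | float",
    solute: str,
    conc: float,
    temp: float,
) -> float:
    if isinstance(h_surface, HydrationTable):
        return h_surface.lookup(solute, conc, temp, extrapolate=True)
    if isinstance(h_surface, Mapping):
        return float(h_surface[solute])
    return float(h_surface)


def generate_ice_dataset(
    registry: SoluteRegistry,
    h_surface: "HydrationTable | Mapping[str, float] | float",
    solutes: "Sequence[str]",
    concentrations: "Sequence[float]",
    temperatures: "Sequence[float]",
    cfg: GeneratorConfig = GeneratorConfig(),
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> IceContentDataset:
    """Replicated ice-content table over a (solute × concentration × T) grid.

    Each cell's truth is the forward ice-curve model at the surface's
    hydration number; replicates add ``N(0, noise_sd_ice)`` and are clamped
    to [0, 100].  Cells whose temperature is at/above the melting point are
    emitted with ice 0 and flag ``above_melting``.
    """
    rng = cfg.rng()
    rows = []
    for name in solutes:
        spec = registry.get(name)
        for conc in concentrations:
            comp = SolutionComposition.single(spec, float(conc))
            for temp in temperatures:
                h = _h_lookup(h_surface, spec.name, float(conc), float(temp))
                point = ice_content(comp, h, float(temp), constants)
                for rep in range(1, cfg.replicates + 1):
                    noisy = point.ice_content_pct + rng.normal(0.0, cfg.noise_sd_ice)
                    rows.append(
                        {
                            "solute": spec.name,
                            "concentration_pct": float(conc),
                            "temperature_c": float(temp),
                            "replicate": rep,
                            "ice_pct": float(np.clip(noisy, 0.0, 100.0))
                            if point.valid
                            else 0.0,
                            "flag": "" if point.valid else "above_melting",
                        }
                    )
    return IceContentDataset(pd.DataFrame(rows))


def _core_temp_profile(
    t_min: np.ndarray,
    lag_min: float,
    total_min: float,
    start_c: float,
    plateau_c: float,
    end_c: float,
) -> np.ndarray:
    """Smooth core-temperature truth: exponential rise to the melting
    plateau (within 2 % of it by the lag time), then relaxation toward the
    ambient end temperature once melting completes."""
    tau_rise = max(lag_min, 1e-6) / 4.0
    temp = plateau_c - (plateau_c - start_c) * np.exp(-t_min / tau_rise)
    after = t_min > total_min
    t_at_total = plateau_c - (plateau_c - start_c) * np.exp(-total_min / tau_rise)
    tau_tail = max(total_min * 0.05, 1e-6)
    temp[after] = end_c - (end_c - t_at_total) * np.exp(-(t_min[after] - total_min) / tau_tail)
    return temp


def generate_melting_curve(
    lag_min: float,
    rate_pct_per_min: float,
    total_time_min: float,
    initial_mass_g: float = 60.0,
    temp_profile: tuple[float, float, float] = (-18.0, -0.5, 20.0),
    cfg: GeneratorConfig = GeneratorConfig(),
    tail_fraction: float = 0.2,
) -> MeltingCurve:
    """Melting curve with lag / fast-phase / plateau drip shape.

    Drip mass is 0 until ``lag_min``, rises at ``rate_pct_per_min`` (% of
    initial mass per minute) until ``total_time_min`` and plateaus after;
    the implied final melted fraction ``rate·(total−lag)/100`` must lie in
    (0, 1].  ``temp_profile = (start, melting plateau, end)`` in °C.  The
    recording continues ``tail_fraction`` beyond the total time.  Additive
    seeded noise; cumulative mass forced non-decreasing afterwards.
    """
    if not 0 <= lag_min < total_time_min:
        raise ValueError("need 0 ≤ lag < total melting time")
    if rate_pct_per_min <= 0 or initial_mass_g <= 0:
        raise ValueError("rate and initial mass must be > 0")
    melted_frac = rate_pct_per_min * (total_time_min - lag_min) / 100.0
    if not 0 < melted_frac <= 1.0:
        raise ValueError(
            f"infeasible parameters: rate·(total−lag) = {100 * melted_frac:.1f} % "
            "of the initial mass"
        )
    rng = cfg.rng()
    t_s = np.arange(0.0, total_time_min * (1 + tail_fraction) * 60.0, cfg.sampling_interval_s)
    t_min = t_s / 60.0

    slope_g_per_min = rate_pct_per_min * initial_mass_g / 100.0
    drip = np.clip((t_min - lag_min) * slope_g_per_min, 0.0, melted_frac * initial_mass_g)
    drip = drip + rng.normal(0.0, cfg.noise_sd_mass, drip.shape)
    drip = np.maximum.accumulate(np.clip(drip, 0.0, initial_mass_g))

    start_c, plateau_c, end_c = temp_profile
    temp = _core_temp_profile(t_min, lag_min, total_time_min, start_c, plateau_c, end_c)
    temp = temp + rng.normal(0.0, cfg.noise_sd_temp, temp.shape)

    return MeltingCurve(
        time_s=t_s, drip_mass_g=drip, core_temp_c=temp, initial_mass_g=initial_mass_g
    )


def melting_curve_truth(
    lag_min: float,
    rate_pct_per_min: float,
    total_time_min: float,
    temp_profile: tuple[float, float, float] = (-18.0, -0.5, 20.0),
) -> MeltingParameters:
    """Noise-free ground-truth parameters of :func:`generate_melting_curve`."""
    start_c, plateau_c, end_c = temp_profile
    t = np.array([lag_min, total_time_min])
    truth_temps = _core_temp_profile(t, lag_min, total_time_min, start_c, plateau_c, end_c)
    return MeltingParameters(
        total_melting_time_min=total_time_min,
        lag_time_min=lag_min,
        melting_rate_pct_per_min=rate_pct_per_min,
        onset_temperature_c=float(truth_temps[0]),
        temp_increase_rate_c_per_min=float((truth_temps[1] - start_c) / total_time_min),
    )


def generate_dsc_trace(
    ice_pct: float,
    peak_center_c: float = -2.0,
    peak_width_c: float = 1.5,
    drift_slope: float = 0.0,
    cfg: GeneratorConfig = GeneratorConfig(),
    temp_range_c: tuple[float, float] = (-40.0, 20.0),
    heating_rate_c_per_min: float = 1.0,
    dt_s: float = 1.0,
    sample_mass_mg: float = 11.0,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> DSCTrace:
    """Final heating ramp with a Gaussian melting endotherm.

    The peak's analytic area over time is ``ice_pct · 334 / 100`` J per g
    of sample (the pure-ice normalisation), placed at ``peak_center_c``
    with standard deviation ``peak_width_c`` on a linear baseline of slope
    ``drift_slope`` (J·s⁻¹·g⁻¹ per s), plus seeded Gaussian noise.
    """
    if peak_width_c <= 0:
        raise ValueError("peak width must be > 0")
    if not 0 <= ice_pct <= 100:
        raise ValueError("ice_pct must be in [0, 100]")
    lo, hi = temp_range_c
    if not lo < peak_center_c < hi:
        raise ValueError("peak centre outside the trace window")
    rng = cfg.rng()
    ramp_c_per_s = heating_rate_c_per_min / 60.0
    t_s = np.arange(0.0, (hi - lo) / ramp_c_per_s + dt_s, dt_s)
    temp = lo + ramp_c_per_s * t_s
    area_j_per_g = ice_pct * constants.latent_heat_ice / 100.0
    gauss_per_c = np.exp(-0.5 * ((temp - peak_center_c) / peak_width_c) ** 2) / (
        peak_width_c * np.sqrt(2.0 * np.pi)
    )
    heat_flow = area_j_per_g * gauss_per_c * ramp_c_per_s  # integrates to area over time
    heat_flow = heat_flow + drift_slope * t_s
    heat_flow = heat_flow + rng.normal(0.0, cfg.noise_sd_heatflow, heat_flow.shape)
    return DSCTrace(
        time_s=t_s,
        temperature_c=temp,
        heat_flow=heat_flow,
        sample_mass_mg=sample_mass_mg,
        annealing_temperature_c=None,
    )
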