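"""Physical-property extraction for frozen model systems.

Melting tests record, every 10 s, the cumulative mass dripping off a
thawing sample and its core temperature.  Five parameters summarise such a
curve: total melting time, lag time (melt onset), melting rate (slope of
the fast, near-linear phase), onset temperature (core temperature at the
lag time) and the mean rate of core-temperature increase.

Hardness tests penetrate a frozen sample with a small cylindrical probe;
the stress at the first force peak (force over probe-tip area) is the
hardness in MPa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MeltingCurve",
    "MeltingParameters",
    "PenetrationTrace",
    "extract_melting_parameters",
    "hardness_from_penetration",
    "linear_fit_r2",
]


@dataclass
class MeltingCurve:
    """Drip-mass and core-temperature time series of one melting test."""

    time_s: np.ndarray
    drip_mass_g: np.ndarray  # cumulative
    core_temp_c: np.ndarray
    initial_mass_g: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.drip_mass_g = np.asarray(self.drip_mass_g, dtype=float)
        self.core_temp_c = np.asarray(self.core_temp_c, dtype=float)
        n = self.time_s.size
        if not (self.drip_mass_g.size == n == self.core_temp_c.size) or n < 3:
            raise ValueError("time, drip mass and core temperature must share length ≥ 3")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(self.drip_mass_g) < -1e-9):
            raise ValueError("cumulative drip mass must be non-decreasing")
        if self.initial_mass_g <= 0:
            raise ValueError("initial mass must be > 0")
        if self.drip_mass_g.max() > self.initial_mass_g * 1.05:
            raise ValueError("drip mass exceeds initial sample mass")


@dataclass(frozen=True)
class MeltingParameters:
    """The five melting-curve summary parameters."""

    total_melting_time_min: float
    lag_time_min: float
    melting_rate_pct_per_min: float  # % of initial mass per minute
    onset_temperature_c: float
    temp_increase_rate_c_per_min: float


@dataclass
class PenetrationTrace:
    """Force–displacement record of a probe-penetration hardness test."""

    displacement_mm: np.ndarray
    force_n: np.ndarray
    probe_diameter_mm: float = 4.0

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.force_n.size == 0:
            raise ValueError("empty penetration trace")
        if self.probe_diameter_mm <= 0:
            raise ValueError("probe diameter must be > 0")


def _interp_at(t: float, time_s: np.ndarray, values: np.ndarray) -> float:
    return float(np.interp(t, time_s, values))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge-corrected (partial-window) ends."""
    if window <= 1 or values.size < window:
        return values
    kernel = np.ones(window)
    return np.convolve(values, kernel, mode="same") / np.convolve(
        np.ones_like(values), kernel, mode="same"
    )


def extract_melting_parameters(
    curve: MeltingCurve,
    drop_threshold_g: float = 0.5,
    fast_band: tuple[float, float] = (0.2, 0.8),
    end_epsilon: float = 0.005,
    temp_smooth_window: int = 3,
) -> MeltingParameters:
    """Extract the five melting parameters from one curve.

    * **Total melting time**: first time the cumulative drip mass reaches
      ``(1 − end_epsilon)`` of its final value ("last droplet" is not
      machine-detectable exactly; the 0.5 % tail is the deterministic
      surrogate).
    * **Melting rate**: OLS slope of drip mass (as % of initial mass) vs.
      time over the fast-phase band — samples between 20 % and 80 % of the
      final drip mass by default.
    * **Lag time**: the x-intercept of that fast-phase line.  Extrapolating
      the linear phase back to zero melt locates the onset independent of
      the detection threshold; ``drop_threshold_g`` only decides whether
      melting occurred at all.
    * **Onset temperature**: core temperature (lightly smoothed) linearly
      interpolated at the lag time.
    * **Temperature-increase rate**: (core temperature at the total melting
      time − initial core temperature) / total melting time.
    """
    t = curve.time_s
    drip = curve.drip_mass_g
    final = float(drip[-1])
    if final <= drop_threshold_g:
        raise ValueError("no melt detected: final drip mass below the drop threshold")

    # total melting time: first arrival within end_epsilon of the final mass
    idx_end = int(np.argmax(drip >= (1.0 - end_epsilon) * final))
    total_min = t[idx_end] / 60.0
    if total_min <= 0:
        raise ValueError("degenerate curve: melt complete at t = 0")

    lo, hi = fast_band
    band = (drip >= lo * final) & (drip <= hi * final)
    if band.sum() < 3:
        raise ValueError(
            f"fewer than 3 samples in the {100*lo:.0f}–{100*hi:.0f} % fast-melting band"
        )
    pct = 100.0 * drip[band] / curve.initial_mass_g
    t_min = t[band] / 60.0
    fit = stats.linregress(t_min, pct)
    if fit.slope <= 0:
        raise ValueError("non-positive fast-phase slope; curve is not melting")
    lag_min = max(-fit.intercept / fit.slope, 0.0)

    temp = _moving_average(curve.core_temp_c, temp_smooth_window)
    onset_temp = _interp_at(lag_min * 60.0, t, temp)

    temp_end = _interp_at(total_min * 60.0, t, temp)
    temp_rate = (temp_end - curve.core_temp_c[0]) / total_min

    return MeltingParameters(
        total_melting_time_min=float(total_min),
        lag_time_min=float(lag_min),
        melting_rate_pct_per_min=float(fit.slope),
        onset_temperature_c=float(onset_temp),
        temp_increase_rate_c_per_min=float(temp_rate),
    )


def hardness_from_penetration(trace: PenetrationTrace, smooth_window: int = 3) -> float:
    """Hardness in MPa: stress at the FIRST force peak of a penetration test.

    Peak detection runs on a moving-average-smoothed copy (window 3 by
    default): the first interior sample exceeding both neighbours.  The
    reported force is the raw maximum in that sample's immediate
    neighbourhood, divided by the probe-tip area.  A trace with no interior
    peak (monotone or flat) falls back to the global maximum with a warning.
    """
    force = trace.force_n
    smoothed = _moving_average(force, smooth_window)

    area_m2 = math.pi * (trace.probe_diameter_mm / 2.0 / 1000.0) ** 2
    peak_force = None
    for i in range(1, force.size - 1):
        if smoothed[i] > smoothed[i - 1] and smoothed[i] > smoothed[i + 1]:
            peak_force = float(force[max(i - 1, 0) : i + 2].max())
            break
    if peak_force is None:
        peak_force = float(force.max())
        warnings.warn(
            "no interior force peak found; using the global maximum", stacklevel=2
        )
    return peak_force / area_m2 / 1e6


def linear_fit_r2(x, y) -> float:
    """Coefficient of determination of the OLS fit y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; slope is unidentifiable")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
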