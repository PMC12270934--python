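"""Effective hydration surfaces: fitting and prediction.

The effective hydration number ``h`` of an anti-freeze agent — the average
moles of water bound per mole of solute, as seen by the freezing
equilibrium — is temperature- and concentration-dependent.  This module
builds a discrete ``h(solute, c, T)`` table from replicated ice-content
measurements (one closed-form inversion per cell) and predicts ice curves
from such a table.

Replicates are averaged before inversion by default, matching the
convention that tabulated hydration numbers are computed from averaged
measurements; the alternative (invert each replicate, then average the
``h`` values) is available because the two differ under noise (the
inversion is affine in ice content, so they coincide only in expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .solutes import SoluteRegistry, SolutionComposition
from .thermo import (
    HydrationAssignment,
    IceCurvePoint,
    hydration_number_from_point,
    ice_content,
)

__all__ = ["IceContentDataset", "HydrationTable", "fit_hydration_table", "predict_ice_curve"]

DATASET_COLUMNS = ["solute", "concentration_pct", "temperature_c", "replicate", "ice_pct"]

InterpolationPolicy = Literal["nearest", "linear-in-T", "bilinear"]


@dataclass
class IceContentDataset:
    """Replicated ice-content measurements keyed by (solute, c %, T °C)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if df.empty:
            raise ValueError("empty ice-content dataset")
        bad = df[(df["ice_pct"] < 0) | (df["ice_pct"] > 100)]
        if not bad.empty:
            raise ValueError(f"ice_pct outside [0, 100] in {len(bad)} record(s)")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "IceContentDataset":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self.records[DATASET_COLUMNS].to_csv(path, index=False)


@dataclass
class HydrationTable:
    """Discrete effective-hydration surface with an interpolation policy.

    ``nearest`` (default) returns the nearest tabulated cell — the honest
    choice when only discrete cells were measured.  ``linear-in-T``
    interpolates in temperature at an exactly matching concentration;
    ``bilinear`` interpolates in both coordinates.  Flagged (negative-h)
    cells are excluded from lookup.
    """

    entries: list[HydrationAssignment]
    interpolation: InterpolationPolicy = "nearest"

    def __post_init__(self) -> None:
        keys = [(e.solute, e.concentration_pct, e.temperature) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (solute, concentration, temperature) keys")

    def _cells(self, solute: str) -> list[HydrationAssignment]:
        cells = [
            e for e in self.entries if e.solute.lower() == solute.lower() and not e.flagged
        ]
        if not cells:
            raise KeyError(f"no usable hydration cells for solute {solute!r}")
        return cells

    def lookup(
        self,
        solute: str,
        concentration_pct: float,
        temperature_c: float,
        extrapolate: bool = False,
    ) -> float:
        """Hydration number at (c, T) under the table's policy.

        Outside the tabulated hull, ``nearest`` and the interpolating
        policies refuse unless ``extrapolate=True`` (then: nearest cell /
        hull-clamped interpolation).
        """
        cells = self._cells(solute)
        temps = np.array([e.temperature for e in cells])
        concs = np.array([e.concentration_pct for e in cells])
        hs = np.array([e.h for e in cells])

        inside_t = temps.min() - 1e-9 <= temperature_c <= temps.max() + 1e-9
        inside_c = concs.min() - 1e-9 <= concentration_pct <= concs.max() + 1e-9
        if not extrapolate and not (inside_t and inside_c):
            raise ValueError(
                f"({concentration_pct} %, {temperature_c} °C) outside the fitted hull for "
                f"{solute!r}; pass extrapolate=True to use the nearest/clamped value"
            )

        if self.interpolation == "nearest":
            # scale-free nearest: rank by (ΔT, Δc) with Δc dominant so the
            # matching concentration series is always preferred
            d = np.hypot(temps - temperature_c, 10.0 * (concs - concentration_pct))
            return float(hs[int(np.argmin(d))])

        if self.interpolation == "linear-in-T":
            at_c = np.isclose(concs, concentration_pct)
            if not at_c.any():
                raise ValueError(
                    f"linear-in-T policy requires cells at concentration {concentration_pct} %"
                )
            order = np.argsort(temps[at_c])
            t_sorted = temps[at_c][order]
            h_sorted = hs[at_c][order]
            t_eval = np.clip(temperature_c, t_sorted[0], t_sorted[-1])
            return float(np.interp(t_eval, t_sorted, h_sorted))

        if self.interpolation == "bilinear":
            from scipy.interpolate import griddata

            t_eval = np.clip(temperature_c, temps.min(), temps.max())
            c_eval = np.clip(concentration_pct, concs.min(), concs.max())
            val = griddata(
                np.column_stack([temps, concs]), hs, [(t_eval, c_eval)], method="linear"
            )[0]
            if np.isnan(val):  # degenerate hull (single line of cells)
                val = griddata(
                    np.column_stack([temps, concs]), hs, [(t_eval, c_eval)], method="nearest"
                )[0]
            return float(val)

        raise ValueError(f"unknown interpolation policy {self.interpolation!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "solute": [e.solute for e in self.entries],
                "concentration_pct": [e.concentration_pct for e in self.entries],
                "temperature_c": [e.temperature for e in self.entries],
                "h": [e.h for e in self.entries],
                "flag": ["negative_h" if e.flagged else "" for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, interpolation: InterpolationPolicy = "nearest") -> "HydrationTable":
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        entries = [
            HydrationAssignment(
                solute=str(r["solute"]),
                concentration_pct=float(r["concentration_pct"]),
                temperature=float(r["temperature_c"]),
                h=float(r["h"]),
                flagged=bool(str(r.get("flag", "")).strip()),
            )
            for _, r in df.iterrows()
        ]
        return cls(entries, interpolation=interpolation)


def fit_hydration_table(
    data: IceContentDataset,
    registry: SoluteRegistry,
    mode: Literal["mean-then-invert", "invert-then-mean"] = "mean-then-invert",
    interpolation: InterpolationPolicy = "nearest",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> HydrationTable:
    """Invert replicated ice contents into an effective-hydration table.

    Each (solute, concentration, temperature) group yields one cell.
    Negative fitted ``h`` (measurement inconsistent with the model) is kept
    with ``flagged=True`` rather than clamped, so the surface is not biased.
    """
    df = data.records
    unresolved = sorted({s for s in df["solute"].unique() if s not in registry})
    if unresolved:
        raise KeyError(f"solutes not in registry: {unresolved}")

    entries: list[HydrationAssignment] = []
    grouped = df.groupby(["solute", "concentration_pct", "temperature_c"], sort=True)
    for (solute, conc, temp), group in grouped:
        spec = registry.get(solute)
        comp = SolutionComposition.single(spec, float(conc))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative-h warning becomes the cell flag
            if mode == "mean-then-invert":
                h = hydration_number_from_point(
                    comp, float(temp), float(group["ice_pct"].mean()), constants
                )
            elif mode == "invert-then-mean":
                hs = [
                    hydration_number_from_point(comp, float(temp), float(v), constants)
                    for v in group["ice_pct"]
                ]
                h = float(np.mean(hs))
            else:
                raise ValueError(f"unknown replicate mode {mode!r}")
        entries.append(
            HydrationAssignment(
                solute=solute,
                concentration_pct=float(conc),
                temperature=float(temp),
                h=float(h),
                flagged=h < 0,
            )
        )
    return HydrationTable(entries, interpolation=interpolation)


def predict_ice_curve(
    comp: SolutionComposition,
    table: HydrationTable,
    temperatures_c,
    extrapolate: bool = False,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[IceCurvePoint]:
    """Predict the ice curve of ``comp`` from a fitted hydration table.

    At each temperature the hydration number of every solute is looked up
    (at that solute's premix concentration) under the table's interpolation
    policy, then the forward ice-curve model is evaluated.
    """
    points = []
    for t in temperatures_c:
        h_by_solute = {
            spec.name: table.lookup(spec.name, pct, float(t), extrapolate=extrapolate)
            for spec, pct in comp.solutes
        }
        points.append(ice_content(comp, h_by_solute, float(t), constants))
    return points
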