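"""CSV schemas shared by the library, generators and CLI.

All files are UTF-8, comma-separated, '.' decimal, with a mandatory header
row.  Scalar metadata (sample mass, probe diameter, sign convention …)
travels in leading ``# key=value`` comment lines so each file stays a
single self-describing artifact.  Every writer's output is accepted by its
reader with values intact (floats round-trip via shortest-repr formatting).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dsc import DSCTrace
from .props import MeltingCurve, PenetrationTrace
from .thermo import IceCurvePoint

__all__ = [
    "read_table",
    "write_table",
    "write_melting_curve",
    "read_melting_curve",
    "write_penetration",
    "read_penetration",
    "write_dsc_trace",
    "read_dsc_trace",
    "write_ice_curve",
    "read_ice_curve",
]


def _format_value(v: Any) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def write_table(path, df: pd.DataFrame, metadata: "dict[str, Any] | None" = None) -> None:
    """Write a DataFrame with optional ``# key=value`` metadata lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={_format_value(value)}\n")
        df.to_csv(fh, index=False)


def read_table(
    path, required: "list[str] | None" = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV with leading ``# key=value`` metadata lines.

    Returns (data, metadata).  Missing required columns raise; unknown
    extra columns only warn.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    skip = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required column(s) {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path.name}: ignoring unknown column(s) {extra}", stacklevel=2)
    return df, metadata


# -- melting curves ---------------------------------------------------------

def write_melting_curve(path, curve: MeltingCurve) -> None:
    df = pd.DataFrame(
        {
            "time_s": curve.time_s,
            "drip_mass_g": curve.drip_mass_g,
            "core_temp_C": curve.core_temp_c,
        }
    )
    write_table(path, df, {"initial_mass_g": float(curve.initial_mass_g)})


def read_melting_curve(path) -> MeltingCurve:
    df, meta = read_table(path, required=["time_s", "drip_mass_g", "core_temp_C"])
    if "initial_mass_g" not in meta:
        raise ValueError(f"{Path(path).name}: missing '# initial_mass_g=' header")
    return MeltingCurve(
        time_s=df["time_s"].to_numpy(),
        drip_mass_g=df["drip_mass_g"].to_numpy(),
        core_temp_c=df["core_temp_C"].to_numpy(),
        initial_mass_g=float(meta["initial_mass_g"]),
    )


# -- penetration traces -----------------------------------------------------

def write_penetration(path, trace: PenetrationTrace) -> None:
    df = pd.DataFrame(
        {"displacement_mm": trace.displacement_mm, "force_N": trace.force_n}
    )
    write_table(path, df, {"probe_diameter_mm": float(trace.probe_diameter_mm)})


def read_penetration(path) -> PenetrationTrace:
    df, meta = read_table(path, required=["displacement_mm", "force_N"])
    return PenetrationTrace(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_n=df["force_N"].to_numpy(),
        probe_diameter_mm=float(meta.get("probe_diameter_mm", 4.0)),
    )


# -- DSC traces -------------------------------------------------------------

def write_dsc_trace(path, trace: DSCTrace) -> None:
    """Heat flow is stored in mW (instrument units); J·s⁻¹·g⁻¹ × sample mass."""
    mw = trace.heat_flow * trace.sample_mass_mg  # J/s/g · mg = mW
    df = pd.DataFrame(
        {"time_s": trace.time_s, "temp_C": trace.temperature_c, "heatflow_mW": mw}
    )
    meta: dict[str, Any] = {
        "sample_mass_mg": float(trace.sample_mass_mg),
        "sign_convention": "endo_up",
    }
    if trace.annealing_temperature_c is not None:
        meta["anneal_temp_C"] = float(trace.annealing_temperature_c)
    write_table(path, df, meta)


def read_dsc_trace(path) -> DSCTrace:
    df, meta = read_table(path, required=["time_s", "temp_C", "heatflow_mW"])
    if "sample_mass_mg" not in meta:
        raise ValueError(f"{Path(path).name}: missing '# sample_mass_mg=' header")
    mass_mg = float(meta["sample_mass_mg"])
    sign = meta.get("sign_convention", "endo_up")
    if sign not in ("endo_up", "endo_down"):
        raise ValueError(f"unknown sign_convention {sign!r}")
    anneal = meta.get("anneal_temp_C")
    return DSCTrace(
        time_s=df["time_s"].to_numpy(),
        temperature_c=df["temp_C"].to_numpy(),
        heat_flow=df["heatflow_mW"].to_numpy() / mass_mg,
        sample_mass_mg=mass_mg,
        annealing_temperature_c=float(anneal) if anneal is not None else None,
        endotherm_positive=(sign == "endo_up"),
    )


# -- ice curves -------------------------------------------------------------

def write_ice_curve(path, solute: str, concentration_pct: float, points) -> None:
    df = pd.DataFrame(
        {
            "solute": solute,
            "concentration_pct": concentration_pct,
            "temperature_C": [p.temperature for p in points],
            "ice_pct": [p.ice_content_pct for p in points],
            "valid": [p.valid for p in points],
        }
    )
    write_table(path, df)


def read_ice_curve(path) -> pd.DataFrame:
    df, _ = read_table(
        path, required=["solute", "concentration_pct", "temperature_C", "ice_pct", "valid"]
    )
    return df
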