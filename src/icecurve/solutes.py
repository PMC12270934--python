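"""Anti-freeze agents and solution compositions.

A :class:`SoluteSpec` identifies one anti-freeze agent by its molecular
weight and degree of dissociation ``i`` (the effective number of particles
per formula unit; 1 for non-electrolytes, 2 for an ideal 1:1 salt).  A
:class:`SolutionComposition` is the premix: masses of water and solutes on
a fixed basis (100 g of sample by default), from which molalities and mole
numbers are derived.

A small registry of the agents commonly screened as cryoprotectants in
frozen-dessert model systems (glucose, sucrose, maltodextrin, ethanol,
xylitol, NaCl) ships with the package as a CSV and can be extended or
replaced by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SoluteSpec",
    "SolutionComposition",
    "SoluteRegistry",
    "load_registry",
]


@dataclass(frozen=True)
class SoluteSpec:
    """One anti-freeze agent.

    ``molecular_weight`` in g·mol⁻¹; ``dissociation_degree`` is the
    colligative particle count per formula unit (≥ 1).
    """

    name: str
    molecular_weight: float
    dissociation_degree: float = 1.0

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.dissociation_degree < 1:
            raise ValueError(f"{self.name}: dissociation_degree must be ≥ 1")


@dataclass(frozen=True)
class SolutionComposition:
    """Premix composition: (solute, % w/w of total sample) pairs on a mass basis.

    The basis mass (default 100 g) fixes the bookkeeping: water mass is the
    basis minus the summed solute masses and must remain positive.
    """

    solutes: tuple[tuple[SoluteSpec, float], ...]
    basis_mass: float = 100.0

    def __init__(
        self,
        solutes: "list[tuple[SoluteSpec, float]] | tuple[tuple[SoluteSpec, float], ...]",
        basis_mass: float = 100.0,
    ) -> None:
        object.__setattr__(self, "solutes", tuple(solutes))
        object.__setattr__(self, "basis_mass", float(basis_mass))
        self._validate()

    def _validate(self) -> None:
        if self.basis_mass <= 0:
            raise ValueError("basis_mass must be > 0")
        total = 0.0
        for spec, pct in self.solutes:
            if not 0 < pct < 100:
                raise ValueError(f"{spec.name}: mass fraction {pct} % outside (0, 100)")
            total += pct
        if total >= 100:
            raise ValueError(f"solute fractions sum to {total} % ≥ 100 %")

    # -- mass bookkeeping ---------------------------------------------------

    @property
    def solute_mass(self) -> float:
        """Total solute mass, g."""
        return sum(pct for _, pct in self.solutes) * self.basis_mass / 100.0

    @property
    def water_mass(self) -> float:
        """Water mass, g (basis minus solutes)."""
        return self.basis_mass - self.solute_mass

    def solute_moles(self) -> dict[str, float]:
        """Moles of each solute (formula units, not dissociated particles)."""
        return {
            spec.name: pct * self.basis_mass / 100.0 / spec.molecular_weight
            for spec, pct in self.solutes
        }

    @property
    def total_solute_moles(self) -> float:
        return sum(self.solute_moles().values())

    @property
    def water_moles(self) -> float:
        from .constants import DEFAULT_CONSTANTS

        return self.water_mass / DEFAULT_CONSTANTS.molar_mass_water

    @classmethod
    def single(
        cls, spec: SoluteSpec, concentration_pct: float, basis_mass: float = 100.0
    ) -> "SolutionComposition":
        """Convenience constructor for a one-solute premix."""
        return cls([(spec, concentration_pct)], basis_mass=basis_mass)


class SoluteRegistry:
    """Name → :class:`SoluteSpec` lookup backed by a CSV table."""

    def __init__(self, specs: "list[SoluteSpec]") -> None:
        self._by_name = {s.name.lower(): s for s in specs}

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get(self, name: str) -> SoluteSpec:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            known = ", ".join(sorted(self._by_name))
            raise KeyError(f"unknown solute {name!r}; registry has: {known}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self],
                "mw_g_per_mol": [s.molecular_weight for s in self],
                "dissociation_degree": [s.dissociation_degree for s in self],
            }
        )

    @classmethod
    def from_csv(cls, path: "str | Path") -> "SoluteRegistry":
        df = pd.read_csv(path)
        required = {"name", "mw_g_per_mol", "dissociation_degree"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
        specs = [
            SoluteSpec(str(r["name"]), float(r["mw_g_per_mol"]), float(r["dissociation_degree"]))
            for _, r in df.iterrows()
        ]
        return cls(specs)


def load_registry(path: "str | Path | None" = None) -> SoluteRegistry:
    """Load a solute registry; with no path, the bundled default table."""
    if path is not None:
        return SoluteRegistry.from_csv(path)
    ref = resources.files("icecurve").joinpath("data/solutes.csv")
    with resources.as_file(ref) as p:
        return SoluteRegistry.from_csv(p)
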