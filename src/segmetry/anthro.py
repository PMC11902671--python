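"""Anthropometric reference table: per-segment mass fraction, density, length.

The published body-segment-inertial-parameter sources are cited, not printed,
so the table is an input: a CSV with columns ``segment, mass_fraction,
density_kgm3, length_fraction``.  The packaged default
(``data/anthropometric_table_synthetic.csv``) is a *synthetic stand-in* with
plausible adult-male values in the Zatsiorsky / de Leva range; replace it
with a population-appropriate table for real studies.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .volumetry import DEFAULT_DENSITY

__all__ = ["AnthropometricTable"]


@dataclass
class AnthropometricTable:
    """Reference fractions/densities keyed by (unsided) segment name."""

    table: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        required = {"segment", "mass_fraction", "density_kgm3", "length_fraction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
        t = self.table.set_index("segment")
        frac = t[["mass_fraction", "length_fraction"]]
        if ((frac <= 0) | (frac >= 1)).any().any():
            raise ValueError("fractions must lie in (0, 1)")
        dens = t["density_kgm3"].dropna()
        if ((dens < 800) | (dens > 1300)).any():
            raise ValueError("densities must lie in [800, 1300] kg/m^3")
        self._t = t

    @staticmethod
    def _base(label: str) -> str:
        for side in ("left_", "right_"):
            if label.startswith(side):
                return label[len(side):]
        return label

    def __contains__(self, label: str) -> bool:
        return self._base(label) in self._t.index

    def _row(self, label: str) -> pd.Series:
        base = self._base(label)
        if base not in self._t.index:
            raise KeyError(f"no anthropometric entry for segment {label!r}")
        return self._t.loc[base]

    def mass_fraction(self, label: str) -> float:
        return float(self._row(label)["mass_fraction"])

    def length_fraction(self, label: str) -> float:
        return float(self._row(label)["length_fraction"])

    def density(self, label: str) -> float:
        """Tabulated density, or 1000 kg/m^3 when no value is available."""
        try:
            d = self._row(label)["density_kgm3"]
        except KeyError:
            return DEFAULT_DENSITY
        return DEFAULT_DENSITY if pd.isna(d) else float(d)

    def reference_mass(self, label: str, body_mass: float) -> float:
        """M_ref = mass fraction x whole-body mass (kg)."""
        return self.mass_fraction(label) * body_mass

    def reference_length(self, label: str, height: float) -> float:
        return self.length_fraction(label) * height

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "AnthropometricTable":
        return cls(pd.read_csv(path), provenance or str(path))

    @classmethod
    def default(cls) -> "AnthropometricTable":
        """The packaged synthetic stand-in table."""
        ref = resources.files("segmetry.data") / "anthropometric_table_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path, provenance="packaged synthetic stand-in")

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)
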