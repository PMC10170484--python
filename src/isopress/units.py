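"""Unit systems and conversion constants.

Two unit systems are supported throughout the package, chosen once per run:

``"real"``
    Lengths in Å, time in ps, energies in kcal/mol, pressures in bar.
    Surface pressures and tensions are reported in mN/m.

``"reduced"``
    Lennard-Jones reduced units (ε = σ = m = k_B = 1).  Surface pressures
    and tensions are reported in ε/σ² (dimensionless here).
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23
KCAL_IN_JOULE = 4184.0

#: 1 kcal mol⁻¹ Å⁻² expressed in mN/m (≈ 694.77).
KCALMOL_PER_A2_IN_MN_PER_M = KCAL_IN_JOULE / AVOGADRO / 1e-20 * 1e3

#: 1 bar·Å expressed in mN/m (10⁵ Pa × 10⁻¹⁰ m × 10³ = 0.01).
BAR_ANGSTROM_IN_MN_PER_M = 1e5 * 1e-10 * 1e3

UNIT_SYSTEMS = ("real", "reduced")


def check_units(units: str) -> str:
    if units not in UNIT_SYSTEMS:
        raise ValueError(f"unknown unit system {units!r}; expected one of {UNIT_SYSTEMS}")
    return units


def surface_pressure_label(units: str) -> str:
    """Output unit label for surface pressures / tensions."""
    return "mN/m" if check_units(units) == "real" else "reduced"


def force_per_length_to_output(value: float, units: str) -> float:
    """Convert a force/length (kcal mol⁻¹ Å⁻² or ε/σ²) to output units."""
    if check_units(units) == "real":
        return value * KCALMOL_PER_A2_IN_MN_PER_M
    return value


def bar_length_to_output(value: float, units: str) -> float:
    """Convert a pressure·length (bar·Å or ε/σ²) to output units."""
    if check_units(units) == "real":
        return value * BAR_ANGSTROM_IN_MN_PER_M
    return value


@dataclass(frozen=True)
class RealUnitsMap:
    """Mapping from reduced LJ units to real units for toy-model fixtures.

    The defaults (σ = 4 Å, ε = 0.3 kcal/mol) are a generic coarse-grained
    bead scale, used only to exercise unit-conversion paths on toy data.
    """

    sigma_angstrom: float = 4.0
    epsilon_kcal_per_mol: float = 0.3

    def length(self, value: float) -> float:
        """Reduced length → Å."""
        return value * self.sigma_angstrom

    def energy(self, value: float) -> float:
        """Reduced energy → kcal/mol."""
        return value * self.epsilon_kcal_per_mol

    def force(self, value: float) -> float:
        """Reduced force → kcal mol⁻¹ Å⁻¹."""
        return value * self.epsilon_kcal_per_mol / self.sigma_angstrom

    def surface_pressure(self, value: float) -> float:
        """Reduced ε/σ² → mN/m."""
        kcal_per_a2 = value * self.epsilon_kcal_per_mol / self.sigma_angstrom**2
        return kcal_per_a2 * KCALMOL_PER_A2_IN_MN_PER_M
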