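"""Physical constants and the two thermal primitives every kinetic stage uses.

All energies inside the package are kcal·mol⁻¹, temperatures K, rate constants
M⁻¹s⁻¹.  Constants are CODATA-2018 exact values; the gas constant in
kcal·mol⁻¹·K⁻¹ follows from them (R = kB·N_A / 4184).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "thermal_frequency",
    "boltzmann_factor",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants plus the package's standard-state conventions."""

    boltzmann_constant: float = 1.380649e-23  # J K^-1 (exact)
    planck_constant: float = 6.62607015e-34  # J s (exact)
    gas_constant_kcal: float = 1.987204e-3  # kcal mol^-1 K^-1
    avogadro_number: float = 6.02214076e23  # mol^-1 (exact)
    # molar concentration of liquid water at 298.15 K (rho = 0.997 g/mL,
    # M = 18.015 g/mol); enters the pKa working equation's 3·log[H2O] term
    water_molarity: float = 55.345  # mol L^-1
    default_temperature: float = 298.15  # K

    def consistency_error(self) -> float:
        """Relative mismatch between R (kcal) and kB·N_A/4184.

        Should be below 1e-6: the two routes to the gas constant must agree
        to at least six significant figures.
        """
        derived = self.boltzmann_constant * self.avogadro_number / 4184.0
        return abs(derived - self.gas_constant_kcal) / self.gas_constant_kcal


CONSTANTS = PhysicalConstants()


def thermal_frequency(temperature: float = CONSTANTS.default_temperature) -> float:
    """kB·T/h, the universal TST prefactor, in s⁻¹.

    At 298.15 K this is 6.2124×10¹² s⁻¹.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return CONSTANTS.boltzmann_constant * temperature / CONSTANTS.planck_constant


def boltzmann_factor(energy_kcal: float, temperature: float = CONSTANTS.default_temperature) -> float:
    """exp(−E/RT) with E in kcal·mol⁻¹.

    Negative energies are allowed and give factors above one (used, e.g., for
    exergonic corrections); RT at 298.15 K is 0.592483 kcal·mol⁻¹.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp(-energy_kcal / (CONSTANTS.gas_constant_kcal * temperature))
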