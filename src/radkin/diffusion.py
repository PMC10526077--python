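"""Diffusion-limited encounter kinetics.

Stokes–Einstein diffusivities feed a Smoluchowski encounter rate constant
k_D, and the Collins–Kimball interpolation combines k_D with the
activation-controlled TST rate into the apparent rate constant
k_app = k_act·k_D/(k_act + k_D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .constants import CONSTANTS
from .model import MediumSpec

__all__ = [
    "DiffusionContext",
    "DEFAULT_K_DIFFUSION",
    "stokes_einstein_diffusivity",
    "smoluchowski_kd",
    "collins_kimball",
    "diffusion_context_for_medium",
]

# calibrated default encounter rate constant (M^-1 s^-1) for a phenolic
# antioxidant + HOO* pair in water at 298.15 K, used when neither explicit
# radii nor an override are given; see docs/methods.md for the calibration
DEFAULT_K_DIFFUSION = 2.30e9

_SANITY_RANGE = (1e7, 1e11)


@dataclass(frozen=True)
class DiffusionContext:
    """Resolved encounter kinetics for one medium (radii in m, k_D in M⁻¹s⁻¹)."""

    k_diffusion: float
    radius_a: Optional[float] = None
    radius_b: Optional[float] = None
    viscosity: Optional[float] = None
    temperature: Optional[float] = None
    source: str = "override"

    def __post_init__(self) -> None:
        if self.k_diffusion <= 0:
            raise ValueError(f"k_diffusion must be positive, got {self.k_diffusion}")
        lo, hi = _SANITY_RANGE
        if not (lo <= self.k_diffusion <= hi):
            warnings.warn(
                f"k_diffusion = {self.k_diffusion:.3g} M^-1 s^-1 lies outside the "
                f"plausible bimolecular range [{lo:g}, {hi:g}]",
                stacklevel=2,
            )


def stokes_einstein_diffusivity(
    radius: float, viscosity: float, temperature: float = 298.15
) -> float:
    """D = kB·T/(6π·η·r) in m²·s⁻¹ for a spherical solute."""
    if radius <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError(
            f"radius, viscosity and temperature must be positive "
            f"(got {radius}, {viscosity}, {temperature})"
        )
    return CONSTANTS.boltzmann_constant * temperature / (
        6.0 * math.pi * viscosity * radius
    )


def smoluchowski_kd(
    radius_a: float, radius_b: float, diff_a: float, diff_b: float
) -> float:
    """Smoluchowski encounter rate constant in M⁻¹s⁻¹.

    k_D = 4π·(r_a + r_b)·(D_a + D_b)·N_A, converted from m³·mol⁻¹·s⁻¹ to
    L·mol⁻¹·s⁻¹ (×10³).
    """
    if min(radius_a, radius_b, diff_a, diff_b) <= 0:
        raise ValueError("radii and diffusivities must be strictly positive")
    k_si = 4.0 * math.pi * (radius_a + radius_b) * (diff_a + diff_b)
    return k_si * CONSTANTS.avogadro_number * 1e3


def collins_kimball(k_activation: float, k_diffusion: float) -> float:
    """Apparent rate constant k_app = k_act·k_D/(k_act + k_D).

    Symmetric in its arguments; reduces to the smaller rate in either limit.
    """
    if k_activation < 0 or k_diffusion < 0:
        raise ValueError("rate constants must be non-negative")
    if k_activation == 0 and k_diffusion == 0:
        raise ValueError("k_activation and k_diffusion cannot both be zero")
    return k_activation * k_diffusion / (k_activation + k_diffusion)


def diffusion_context_for_medium(medium: MediumSpec) -> DiffusionContext:
    """Resolve k_D for a medium.

    Priority: explicit ``diffusion_override``; else Stokes–Einstein +
    Smoluchowski from ``reactant_radii`` (needs exactly two radii); else the
    calibrated default for a phenolic antioxidant/HOO• pair.
    """
    if medium.diffusion_override is not None:
        return DiffusionContext(
            k_diffusion=medium.diffusion_override, source="override"
        )
    if medium.reactant_radii:
        radii = list(medium.reactant_radii.values())
        if len(radii) != 2:
            raise ValueError(
                f"medium {medium.name!r}: need exactly two reactant radii, "
                f"got {len(radii)}"
            )
        ra, rb = radii
        da = stokes_einstein_diffusivity(ra, medium.viscosity, medium.temperature)
        db = stokes_einstein_diffusivity(rb, medium.viscosity, medium.temperature)
        return DiffusionContext(
            k_diffusion=smoluchowski_kd(ra, rb, da, db),
            radius_a=ra,
            radius_b=rb,
            viscosity=medium.viscosity,
            temperature=medium.temperature,
            source="stokes-einstein",
        )
    return DiffusionContext(k_diffusion=DEFAULT_K_DIFFUSION, source="default")
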