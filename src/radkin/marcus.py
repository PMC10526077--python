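"""Marcus theory for single-electron-transfer channels.

The SET activation Gibbs energy is the Marcus parabola
ΔG≠ = (λ/4)·(1 + ΔG⁰/λ)², with the nuclear reorganization energy λ either
given directly or approximated from the vertical energy gap as
λ = ΔE_SET − ΔG⁰_SET.  SET rates use the plain TST prefactor with κ = 1
(no light-particle tunneling coordinate in this treatment).
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import boltzmann_factor, thermal_frequency
from .model import SetParams

__all__ = [
    "MarcusChannel",
    "marcus_barrier",
    "lambda_from_energies",
    "resolve_channel",
    "set_rate",
]


@dataclass(frozen=True)
class MarcusChannel:
    """Resolved Marcus inputs and the derived activation energy (kcal·mol⁻¹)."""

    dG0_set: float
    lambda_reorg: float
    dG_activation_set: float

    def __post_init__(self) -> None:
        if self.lambda_reorg <= 0:
            raise ValueError(f"lambda_reorg must be positive, got {self.lambda_reorg}")
        if self.dG_activation_set < 0:
            raise ValueError("Marcus barrier cannot be negative")


def marcus_barrier(dG0_set: float, lambda_reorg: float) -> float:
    """(λ/4)·(1 + ΔG⁰/λ)² in kcal·mol⁻¹; a perfect square, hence ≥ 0."""
    if lambda_reorg <= 0:
        raise ValueError(f"lambda_reorg must be positive, got {lambda_reorg}")
    return (lambda_reorg / 4.0) * (1.0 + dG0_set / lambda_reorg) ** 2


def lambda_from_energies(dE_set: float, dG0_set: float) -> float:
    """Reorganization energy from the vertical gap: λ = ΔE_SET − ΔG⁰_SET."""
    lam = dE_set - dG0_set
    if lam <= 0:
        raise ValueError(
            "non-positive reorganization energy "
            f"(dE_set={dE_set} kcal/mol, dG0_set={dG0_set} kcal/mol -> lambda={lam})"
        )
    return lam


def resolve_channel(params: SetParams) -> MarcusChannel:
    """Derive λ if needed and evaluate the Marcus barrier."""
    if params.lambda_reorg is not None:
        lam = params.lambda_reorg
    elif params.dE_set is not None:
        lam = lambda_from_energies(params.dE_set, params.dG0_set)
    else:
        raise ValueError(
            "SET kinetics need a reorganization energy: give lambda_reorg or dE_set"
        )
    return MarcusChannel(
        dG0_set=params.dG0_set,
        lambda_reorg=lam,
        dG_activation_set=marcus_barrier(params.dG0_set, lam),
    )


def set_rate(channel: MarcusChannel, sigma: int = 1, temperature: float = 298.15) -> float:
    """σ·(kBT/h)·exp(−ΔG≠_SET/RT) in M⁻¹s⁻¹ (pre-diffusion, κ = 1)."""
    if sigma < 1:
        raise ValueError(f"symmetry number must be >= 1, got {sigma}")
    return sigma * thermal_frequency(temperature) * boltzmann_factor(
        channel.dG_activation_set, temperature
    )
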