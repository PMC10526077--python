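"""Shared domain types: species states, reaction channels, media.

These are plain dataclasses with eager validation; every downstream stage
(speciation, screening, kinetics, aggregation) consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Mechanism(str, Enum):
    """Elementary radical-scavenging channel types.

    HAT — hydrogen atom transfer from an O–H bond to the radical.
    RAF — radical adduct formation at an unsaturated carbon.
    SET — single electron transfer from a (usually deprotonated) phenolate.
    """

    HAT = "HAT"
    RAF = "RAF"
    SET = "SET"


@dataclass(frozen=True)
class EckartBarrier:
    """Asymmetric Eckart barrier parameters for a tunneling correction.

    forward_barrier / reverse_barrier in kcal·mol⁻¹ (zero-point-inclusive
    barrier heights seen from reactants / products), imaginary_wavenumber is
    the magnitude of the transition-state imaginary frequency in cm⁻¹.
    """

    forward_barrier: float
    reverse_barrier: float
    imaginary_wavenumber: float

    def __post_init__(self) -> None:
        if self.forward_barrier <= 0 or self.reverse_barrier <= 0:
            raise ValueError("Eckart barriers must be strictly positive")
        if self.imaginary_wavenumber <= 0:
            raise ValueError("imaginary wavenumber must be strictly positive")


@dataclass(frozen=True)
class SetParams:
    """Marcus inputs for an electron-transfer channel (kcal·mol⁻¹).

    Either the reorganization energy λ is given directly, or the vertical
    energy gap ΔE_SET is given and λ = ΔE_SET − ΔG⁰_SET is derived.
    """

    dG0_set: float
    lambda_reorg: Optional[float] = None
    dE_set: Optional[float] = None

    def __post_init__(self) -> None:
        # lambda_reorg/dE_set may both be absent for screen-only channels;
        # resolve_channel() enforces their presence when kinetics are computed
        if self.lambda_reorg is not None and self.lambda_reorg <= 0:
            raise ValueError(f"lambda_reorg must be positive, got {self.lambda_reorg}")


@dataclass
class SpeciesState:
    """One protonation state of an antioxidant.

    ``deprotonation_count`` indexes the acid–base ladder (0 = fully
    protonated).  ``mole_fraction`` may be supplied (e.g. a literature value)
    or left None to be computed from pKa values at the medium's pH.
    ``site_descriptors`` maps site labels to descriptor dicts; the key
    ``proton_affinity`` (kcal·mol⁻¹) drives deprotonation-site ranking.
    """

    compound_id: str
    state_id: str
    net_charge: int
    deprotonation_count: int = 0
    mole_fraction: Optional[float] = None
    site_descriptors: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deprotonation_count < 0:
            raise ValueError("deprotonation_count must be >= 0")
        if self.mole_fraction is not None and not (0.0 <= self.mole_fraction <= 1.0):
            raise ValueError(
                f"mole_fraction must lie in [0,1], got {self.mole_fraction}"
            )


@dataclass
class ReactionPathway:
    """One elementary channel of one protonation state against the radical.

    Energies in kcal·mol⁻¹.  Exactly one tunneling source may be given:
    a supplied multiplicative factor ``kappa`` or ``eckart`` parameters;
    SET channels take neither (κ ≡ 1) and require ``set_params``.
    ``k_app_supplied`` optionally carries a precomputed apparent rate
    constant (M⁻¹s⁻¹) used when the run reproduces published rates verbatim.
    """

    compound_id: str
    state_id: str
    mechanism: Mechanism
    site: Optional[str] = None
    dG_reaction: Optional[float] = None
    dG_activation: Optional[float] = None
    symmetry_number: int = 1
    kappa: Optional[float] = None
    eckart: Optional[EckartBarrier] = None
    set_params: Optional[SetParams] = None
    k_app_supplied: Optional[float] = None

    def __post_init__(self) -> None:
        self.mechanism = Mechanism(self.mechanism)
        if not (isinstance(self.symmetry_number, int) and self.symmetry_number >= 1):
            raise ValueError(
                f"symmetry_number must be an integer >= 1, got {self.symmetry_number}"
            )
        if self.kappa is not None and self.eckart is not None:
            raise ValueError("give either a supplied kappa or Eckart parameters, not both")
        if self.mechanism is Mechanism.SET:
            if self.set_params is None:
                raise ValueError("SET pathway requires set_params")
            if self.kappa is not None or self.eckart is not None:
                raise ValueError("SET pathway takes no tunneling correction")
        elif self.set_params is not None:
            raise ValueError("set_params only apply to SET pathways")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")

    @property
    def label(self) -> str:
        site = self.site or "-"
        return f"{self.compound_id}/{self.state_id}/{self.mechanism.value}@{site}"


@dataclass
class MediumSpec:
    """Solvent context for one kinetic scenario.

    pH is present iff the medium is aqueous (lipid-like media carry no acid–
    base equilibrium).  ``diffusion_override`` short-circuits the Stokes–
    Einstein/Smoluchowski estimate with a calibrated diffusion rate constant.
    ``reactant_radii`` maps labels (antioxidant, radical) to radii in metres.
    """

    name: str
    aqueous: bool
    temperature: float = 298.15
    pH: Optional[float] = None
    viscosity: float = 8.91e-4
    reactant_radii: Optional[dict[str, float]] = None
    diffusion_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.aqueous and self.pH is None:
            raise ValueError(f"aqueous medium {self.name!r} needs a pH")
        if not self.aqueous and self.pH is not None:
            raise ValueError(f"non-aqueous medium {self.name!r} must not carry a pH")
        if self.diffusion_override is not None and self.diffusion_override <= 0:
            raise ValueError("diffusion_override must be positive")
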