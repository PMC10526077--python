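"""radkin: radical-scavenging kinetics from thermochemical descriptors.

Acid–base speciation at physiological pH, thermodynamic feasibility
screening, TST rate constants with Eckart tunneling, Marcus electron-transfer
barriers, Collins–Kimball diffusion correction, and pH-weighted overall rate
constants with branching ratios.
"""

from .constants import CONSTANTS, PhysicalConstants, boltzmann_factor, thermal_frequency
from .config import RunConfig, load_config, loads_config
from .diffusion import collins_kimball, smoluchowski_kd, stokes_einstein_diffusivity
from .marcus import lambda_from_energies, marcus_barrier, set_rate
from .model import EckartBarrier, MediumSpec, Mechanism, ReactionPathway, SetParams, SpeciesState
from .pipeline import run_pipeline, write_results
from .report import (
    PathwayRate,
    ScenarioResult,
    branching_ratios,
    compare_to_references,
    overall_rate,
    weight_rate,
)
from .screen import classify_pathway, screen_pathways
from .speciation import fractions_at_ph, pka_from_gibbs, rank_deprotonation_sites
from .synthetic import brute_force_kappa, generate_scenario, recover_parameters
from .tst import eckart_kappa, eckart_transmission, tst_rate

__version__ = "0.1.0"

__all__ = [
    "CONSTANTS", "PhysicalConstants", "boltzmann_factor", "thermal_frequency",
    "RunConfig", "load_config", "loads_config",
    "collins_kimball", "smoluchowski_kd", "stokes_einstein_diffusivity",
    "lambda_from_energies", "marcus_barrier", "set_rate",
    "EckartBarrier", "MediumSpec", "Mechanism", "ReactionPathway", "SetParams",
    "SpeciesState", "run_pipeline", "write_results",
    "PathwayRate", "ScenarioResult", "branching_ratios", "compare_to_references",
    "overall_rate", "weight_rate", "classify_pathway", "screen_pathways",
    "fractions_at_ph", "pka_from_gibbs", "rank_deprotonation_sites",
    "brute_force_kappa", "generate_scenario", "recover_parameters",
    "eckart_kappa", "eckart_transmission", "tst_rate",
]


def fixture_path(name: str):
    """Path to a shipped fixture config (table1_water, table2_pentyl_ethanoate,
    figure3_screen) or data file."""
    from importlib import resources

    candidate = resources.files("radkin.data").joinpath(f"{name}.yaml")
    if not candidate.is_file():
        raise FileNotFoundError(f"no shipped fixture named {name!r}")
    return candidate
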