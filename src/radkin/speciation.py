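"""Acid–base speciation at a given pH.

pKa values come either from the working equation below (pKa from the Gibbs
free energy of the proton-exchange reaction with hydroxide/water clusters) or
directly from the literature; mole fractions of the protonation states follow
the closed-form polyprotic distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS

__all__ = [
    "SpeciationProfile",
    "pka_from_gibbs",
    "fractions_at_ph",
    "rank_deprotonation_sites",
    "speciation_profile",
    "profiles_to_frame",
]

# states with equilibrium population below this are reported but dropped from
# kinetics (an absent form cannot contribute measurable flux)
NEGLIGIBLE_FRACTION = 1e-3


@dataclass
class SpeciationProfile:
    """pKa ladder and state populations of one compound at one pH.

    ``fractions`` maps deprotonation count j (0 = fully protonated) to the
    equilibrium mole fraction.
    """

    compound_id: str
    pH: float
    pka_values: tuple[float, ...]
    fractions: dict[int, float]

    def __post_init__(self) -> None:
        pkas = tuple(self.pka_values)
        if any(b <= a for a, b in zip(pkas, pkas[1:])):
            raise ValueError(f"pKa values must be strictly increasing, got {pkas}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        self.pka_values = pkas

    def dominant_state(self) -> int:
        return max(self.fractions, key=self.fractions.get)


def pka_from_gibbs(dG_sol_kcal: float, temperature: float = 298.15) -> float:
    """pKa from the solution Gibbs energy of the hydroxide-exchange reaction.

    pKa = ΔG_sol/(RT·ln10) + 14 + 3·log₁₀[H₂O]; the +14 and 3·log[H₂O] terms
    account for the water autoionization reference and the three explicit
    water molecules of the thermodynamic cycle.  RT·ln10 = 1.36434 kcal·mol⁻¹
    at 298.15 K.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    rt_ln10 = CONSTANTS.gas_constant_kcal * temperature * math.log(10.0)
    return dG_sol_kcal / rt_ln10 + 14.0 + 3.0 * math.log10(CONSTANTS.water_molarity)


def fractions_at_ph(pka_values: Sequence[float], pH: float) -> dict[int, float]:
    """Equilibrium mole fractions of all protonation states of a polyprotic acid.

    The unnormalized weight of the j-times-deprotonated state is
    10^(j·pH − Σ_{i≤j} pKa_i); weights are normalized to sum to one.  Keys run
    from 0 (fully protonated) to len(pka_values) (fully deprotonated).
    """
    pkas = np.asarray(pka_values, dtype=float)
    if pkas.size == 0:
        raise ValueError("pka_values must be non-empty")
    if np.any(np.diff(pkas) <= 0):
        raise ValueError(f"pKa values must be strictly increasing, got {list(pkas)}")
    j = np.arange(pkas.size + 1)
    exponents = j * pH - np.concatenate(([0.0], np.cumsum(pkas)))
    exponents -= exponents.max()  # overflow guard; normalization cancels it
    weights = 10.0 ** exponents
    fracs = weights / weights.sum()
    return {int(k): float(f) for k, f in zip(j, fracs)}


def rank_deprotonation_sites(
    site_proton_affinities: dict[str, float],
) -> tuple[list[str], bool]:
    """Order acidic sites by increasing proton affinity.

    The site with the lowest PA loses its proton first.  Ties are broken by
    site label; the returned flag is True when any tie occurred.
    """
    if not site_proton_affinities:
        raise ValueError("need at least one site with a proton affinity")
    items = sorted(site_proton_affinities.items(), key=lambda kv: (kv[1], kv[0]))
    values = [v for _, v in items]
    tied = len(set(values)) < len(values)
    return [name for name, _ in items], tied


def speciation_profile(
    compound_id: str, pka_values: Sequence[float], pH: float
) -> SpeciationProfile:
    """Convenience constructor: compute fractions and wrap them in a profile."""
    return SpeciationProfile(
        compound_id=compound_id,
        pH=pH,
        pka_values=tuple(float(p) for p in pka_values),
        fractions=fractions_at_ph(pka_values, pH),
    )


def profiles_to_frame(profiles: Iterable[SpeciationProfile]) -> pd.DataFrame:
    """Tabulate profiles for CSV export (one row per protonation state)."""
    rows = []
    for prof in profiles:
        for j, frac in sorted(prof.fractions.items()):
            rows.append(
                {
                    "compound": prof.compound_id,
                    "deprotonation_count": j,
                    "pH": prof.pH,
                    "pka_values": ";".join(f"{p:g}" for p in prof.pka_values),
                    "mole_fraction": frac,
                    "negligible": frac < NEGLIGIBLE_FRACTION,
                }
            )
    return pd.DataFrame(rows)
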