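"""Conventional transition-state theory with Eckart tunneling.

k = σ·κ·(kB·T/h)·exp(−ΔG≠/RT), with ΔG≠ the 1 M standard-state activation
Gibbs energy in solution, so the expression yields bimolecular rate constants
in M⁻¹s⁻¹ directly.  The tunneling correction κ is the Boltzmann-weighted
ratio of quantum to classical barrier-crossing flux through an asymmetric
Eckart barrier parameterized by the forward and reverse barrier heights and
the magnitude of the transition-state imaginary frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import CONSTANTS, boltzmann_factor, thermal_frequency
from .model import EckartBarrier, ReactionPathway

__all__ = [
    "ThermalRate",
    "tst_rate",
    "eckart_transmission",
    "eckart_kappa",
    "WAVENUMBER_TO_KCAL",
    "NEGLIGIBLE_RATE",
]

# h*c*N_A per cm^-1, in kcal/mol: converts an imaginary wavenumber to the
# energy quantum of the barrier-top mode
WAVENUMBER_TO_KCAL = (
    CONSTANTS.planck_constant * 2.99792458e10 * CONSTANTS.avogadro_number / 4184.0
)

# rates below this are physically irrelevant on any observable timescale and
# are flagged as negligible in reports
NEGLIGIBLE_RATE = 1e-6

# integrate the tunneling integrand up to this many RT above the barrier;
# the truncated tail is < exp(-20) of the classical flux
_ENERGY_SPAN_RT = 20.0


@dataclass(frozen=True)
class ThermalRate:
    """Per-channel activation-controlled rate record (pre-diffusion)."""

    pathway: ReactionPathway
    kappa: float
    k_tst: float  # sigma=1, kappa=1 baseline, M^-1 s^-1
    k_activation: float  # sigma * kappa * k_tst, M^-1 s^-1

    @property
    def negligible(self) -> bool:
        return self.k_activation < NEGLIGIBLE_RATE


def tst_rate(
    dG_activation: float,
    kappa: float = 1.0,
    sigma: int = 1,
    temperature: float = 298.15,
) -> float:
    """σ·κ·(kBT/h)·exp(−ΔG≠/RT) in M⁻¹s⁻¹.

    κ below 1 is accepted (published tables occasionally fold other
    corrections into this factor) but warned about, since an Eckart
    tunneling correction is ≥ 1 by construction.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if sigma < 1:
        raise ValueError(f"symmetry number must be >= 1, got {sigma}")
    if kappa < 1.0:
        warnings.warn(
            f"tunneling factor {kappa} < 1 is impossible for an Eckart barrier; "
            "treating it as an opaque multiplicative correction",
            stacklevel=2,
        )
    return sigma * kappa * thermal_frequency(temperature) * boltzmann_factor(
        dG_activation, temperature
    )


def _cosh_ratio(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """cosh(x)/cosh(y) for x, y >= 0, overflow-safe for large arguments."""
    expo = np.clip(x - y, -745.0, 700.0)
    return np.exp(expo) * (1.0 + np.exp(-2.0 * np.minimum(x, 700.0))) / (
        1.0 + np.exp(-2.0 * np.minimum(y, 700.0))
    )


def eckart_transmission(
    energy: float | np.ndarray,
    forward_barrier: float,
    reverse_barrier: float,
    imaginary_wavenumber: float,
) -> float | np.ndarray:
    """Transmission probability p(E) through an asymmetric Eckart barrier.

    Energies in kcal·mol⁻¹ measured from the reactant asymptote; the barrier
    is parameterized by its forward (V₁) and reverse (V₂) heights and the
    imaginary wavenumber ν̃ of the barrier-top mode.  With
    α₁ = 2πV₁/(hcν̃), α₂ = 2πV₂/(hcν̃), ξ = E/V₁:

        a = 2√(α₁ξ) / (α₁^(-1/2) + α₂^(-1/2))
        b = 2√((ξ−1)α₁ + α₂) / (α₁^(-1/2) + α₂^(-1/2))
        d = 2√(α₁α₂ − π²/4)
        p = [cosh(a+b) − cosh(a−b)] / [cosh(a+b) + cosh(d)]

    p vanishes below the product asymptote (E < V₁ − V₂).  When
    α₁α₂ ≤ π²/4 the barrier is too thin for the bound form; a warning is
    emitted and a classical step function at the barrier top is returned.
    """
    if forward_barrier <= 0 or reverse_barrier <= 0 or imaginary_wavenumber <= 0:
        raise ValueError("Eckart parameters must be strictly positive")
    E = np.asarray(energy, dtype=float)
    if np.any(E < 0):
        raise ValueError("energy must be >= 0")
    hnu = imaginary_wavenumber * WAVENUMBER_TO_KCAL
    alpha1 = 2.0 * math.pi * forward_barrier / hnu
    alpha2 = 2.0 * math.pi * reverse_barrier / hnu

    if alpha1 * alpha2 <= math.pi**2 / 4.0:
        warnings.warn(
            "Eckart barrier too thin for the bound transmission form "
            f"(2πV/hν product {alpha1 * alpha2:.3g} <= π²/4); "
            "falling back to a classical step function",
            stacklevel=2,
        )
        p = (E >= forward_barrier).astype(float)
        return float(p) if np.isscalar(energy) else p

    denom_scale = 1.0 / math.sqrt(alpha1) + 1.0 / math.sqrt(alpha2)
    xi = E / forward_barrier
    a = 2.0 * np.sqrt(alpha1 * xi) / denom_scale
    b_arg = (xi - 1.0) * alpha1 + alpha2
    open_channel = b_arg > 0.0  # E above the product asymptote
    b = 2.0 * np.sqrt(np.where(open_channel, b_arg, 0.0)) / denom_scale
    d = 2.0 * math.sqrt(alpha1 * alpha2 - math.pi**2 / 4.0)

    apb = a + b
    amb = np.abs(a - b)
    # p = (1 - cosh(a-b)/cosh(a+b)) / (1 + cosh(d)/cosh(a+b)), all ratios safe
    p = (1.0 - _cosh_ratio(amb, apb)) / (1.0 + _cosh_ratio(np.full_like(apb, d), apb))
    p = np.where(open_channel, np.clip(p, 0.0, 1.0), 0.0)
    return float(p) if np.isscalar(energy) else p


def eckart_kappa(
    forward_barrier: float,
    reverse_barrier: float,
    imaginary_wavenumber: float,
    temperature: float = 298.15,
) -> float:
    """Eckart tunneling correction κ(T) ≥ 1.

    κ = β·exp(βV₁)·∫₀^∞ p(E)·exp(−βE) dE — the quantum thermal flux divided
    by the classical (step-function) flux.  The integral is evaluated by
    adaptive quadrature in ε = E − V₁ over [−V₁, 20RT], split at the barrier
    top, to 1e-8 relative tolerance or better.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    beta = 1.0 / (CONSTANTS.gas_constant_kcal * temperature)
    v1, v2 = forward_barrier, reverse_barrier

    def integrand(eps: float) -> float:
        # beta * p(V1 + eps) * exp(-beta*eps); exp(beta*V1) folded in here
        return beta * float(
            eckart_transmission(v1 + eps, v1, v2, imaginary_wavenumber)
        ) * math.exp(-beta * eps)

    upper = _ENERGY_SPAN_RT / beta
    # the transmission switches from ~0 to ~1 over a boundary layer of width
    # ~hcν/2π around the barrier top; seed the quadrature with cuts at that
    # scale so narrow layers (small ν) are not stepped over
    width = imaginary_wavenumber * WAVENUMBER_TO_KCAL / (2.0 * math.pi)
    cuts = sorted(
        {
            -v1,
            *(c for c in (-50 * width, -5 * width, 5 * width, 50 * width)
              if -v1 < c < upper),
            0.0,
            upper,
        }
    )
    kappa, err = 0.0, 0.0
    with warnings.catch_warnings():
        # a too-thin barrier warns once per p(E) call; surface it once here
        warnings.simplefilter("once")
        for lo, hi in zip(cuts, cuts[1:]):
            part, part_err = quad(
                integrand, lo, hi, epsabs=1e-14, epsrel=1e-10, limit=400
            )
            kappa += part
            err += part_err
    if kappa <= 0 or not math.isfinite(kappa):
        raise ArithmeticError(f"Eckart quadrature failed: kappa={kappa}, error={err}")
    if err > 1e-6 * kappa:
        raise ArithmeticError(
            f"Eckart quadrature did not converge: estimated error {err:g} "
            f"on kappa {kappa:g}"
        )
    return kappa


def thermal_rate_for_pathway(
    pathway: ReactionPathway, temperature: float = 298.15
) -> ThermalRate:
    """Resolve κ (supplied, Eckart-computed, or 1) and evaluate the TST rate."""
    if pathway.dG_activation is None:
        raise ValueError(f"{pathway.label}: no activation Gibbs energy")
    if pathway.kappa is not None:
        kappa = pathway.kappa
    elif pathway.eckart is not None:
        e: EckartBarrier = pathway.eckart
        kappa = eckart_kappa(
            e.forward_barrier, e.reverse_barrier, e.imaginary_wavenumber, temperature
        )
    else:
        kappa = 1.0
    k_base = thermal_frequency(temperature) * boltzmann_factor(
        pathway.dG_activation, temperature
    )
    k_act = tst_rate(
        pathway.dG_activation, kappa, pathway.symmetry_number, temperature
    )
    return ThermalRate(pathway=pathway, kappa=kappa, k_tst=k_base, k_activation=k_act)
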