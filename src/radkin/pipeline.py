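"""End-to-end scenario evaluation.

For each compound × medium: acid–base speciation → thermodynamic screen →
per-channel kinetics (TST with tunneling for HAT/RAF, Marcus for SET, all
diffusion-corrected via Collins–Kimball) → mole-fraction weighting,
summation into the overall rate constant, and branching ratios.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional

from .config import RunConfig, CompoundSpec
from .diffusion import collins_kimball, diffusion_context_for_medium
from .marcus import resolve_channel, set_rate
from .model import MediumSpec, Mechanism, ReactionPathway, SpeciesState
from .report import (
    PathwayRate,
    ScenarioResult,
    render_json,
    render_markdown,
    results_to_frame,
)
from .screen import classify_pathway
from .speciation import NEGLIGIBLE_FRACTION, fractions_at_ph
from .tst import thermal_rate_for_pathway

__all__ = ["run_pipeline", "write_results", "state_fractions"]


def state_fractions(
    compound: CompoundSpec, medium: MediumSpec
) -> dict[str, float]:
    """Equilibrium mole fraction of each declared state in a medium.

    Aqueous media: supplied per-state fractions take precedence; otherwise
    fractions come from the compound's pKa ladder at the medium pH.  Lipid
    media carry no acid–base equilibrium: the fully protonated (neutral)
    state gets fraction 1, all others 0.
    """
    fractions: dict[str, float] = {}
    if medium.aqueous:
        computed: Optional[dict[int, float]] = None
        if compound.pka_values:
            computed = fractions_at_ph(compound.pka_values, medium.pH)
        elif all(st.deprotonation_count == 0 for st in compound.states):
            computed = {0: 1.0}  # single fully protonated species, no ladder
        for st in compound.states:
            if st.mole_fraction is not None:
                fractions[st.state_id] = st.mole_fraction
            elif computed is not None:
                fractions[st.state_id] = computed.get(st.deprotonation_count, 0.0)
            else:
                raise ValueError(
                    f"{compound.compound_id}/{st.state_id}: no mole fraction supplied "
                    "and no pKa values to compute one"
                )
    else:
        for st in compound.states:
            fractions[st.state_id] = 1.0 if st.deprotonation_count == 0 else 0.0
    return fractions


def _evaluate_pathway(
    pathway: ReactionPathway,
    mole_fraction: float,
    k_diffusion: float,
    temperature: float,
    rate_source: str,
) -> PathwayRate:
    if rate_source == "supplied" and pathway.k_app_supplied is not None:
        if pathway.mechanism is Mechanism.SET:
            ch = resolve_channel(pathway.set_params)
            kappa_or_lambda: Optional[float] = ch.lambda_reorg
            dG_act = ch.dG_activation_set
        else:
            kappa_or_lambda = pathway.kappa
            dG_act = pathway.dG_activation
        return PathwayRate(
            pathway=pathway,
            kappa_or_lambda=kappa_or_lambda,
            dG_activation=dG_act,
            k_activation=None,
            k_diffusion=k_diffusion,
            k_app=pathway.k_app_supplied,
            mole_fraction=mole_fraction,
        )
    if pathway.mechanism is Mechanism.SET:
        ch = resolve_channel(pathway.set_params)
        k_act = set_rate(ch, pathway.symmetry_number, temperature)
        kappa_or_lambda = ch.lambda_reorg
        dG_act = ch.dG_activation_set
    else:
        tr = thermal_rate_for_pathway(pathway, temperature)
        k_act = tr.k_activation
        kappa_or_lambda = tr.kappa
        dG_act = pathway.dG_activation
    k_app = collins_kimball(k_act, k_diffusion) if k_act > 0 else 0.0
    return PathwayRate(
        pathway=pathway,
        kappa_or_lambda=kappa_or_lambda,
        dG_activation=dG_act,
        k_activation=k_act,
        k_diffusion=k_diffusion,
        k_app=k_app,
        mole_fraction=mole_fraction,
    )


def run_pipeline(config: RunConfig) -> list[ScenarioResult]:
    """Evaluate every compound in every medium of a validated config."""
    results: list[ScenarioResult] = []
    for medium in config.media:
        temperature = medium.temperature
        k_diffusion = diffusion_context_for_medium(medium).k_diffusion
        for compound in config.compounds:
            fractions = state_fractions(compound, medium)
            rates: list[PathwayRate] = []
            excluded = []
            for pathway in compound.pathways:
                f = fractions.get(pathway.state_id, 0.0)
                if f < NEGLIGIBLE_FRACTION:
                    continue  # absent protonation state in this medium
                if pathway.mechanism is Mechanism.SET and not medium.aqueous:
                    warnings.warn(
                        f"{pathway.label}: SET is not feasible in non-polar "
                        f"medium {medium.name!r}; skipped",
                        stacklevel=2,
                    )
                    continue
                verdict = classify_pathway(
                    pathway.dG_reaction, config.options.borderline_cutoff, pathway
                )
                if not verdict.retained_for_kinetics:
                    excluded.append(verdict)
                    continue
                sp = pathway.set_params
                has_set_kinetics = sp is not None and (
                    sp.lambda_reorg is not None or sp.dE_set is not None
                )
                if (
                    pathway.dG_activation is None
                    and not has_set_kinetics
                    and pathway.k_app_supplied is None
                ):
                    continue  # screen-only channel: no kinetic descriptors
                rates.append(
                    _evaluate_pathway(
                        pathway, f, k_diffusion, temperature,
                        config.options.rate_source,
                    )
                )
            results.append(
                ScenarioResult(
                    compound_id=compound.compound_id,
                    medium=medium,
                    pathway_rates=rates,
                    excluded=excluded,
                )
            )
    return results


def write_results(
    results: Iterable[ScenarioResult], fmt: str, path: str | Path
) -> Path:
    """Write results as csv, json, or markdown; byte-stable for equal inputs."""
    path = Path(path)
    results = list(results)
    if fmt == "csv":
        frame = results_to_frame(results)
        path.write_text(frame.to_csv(index=False, float_format="%.12g"))
    elif fmt == "json":
        path.write_text(render_json(results) + "\n")
    elif fmt == "markdown":
        path.write_text(render_markdown(results))
    else:
        raise ValueError(f"unknown output format {fmt!r} (csv, json, markdown)")
    return path
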