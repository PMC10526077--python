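"""Aggregation of channel kinetics into overall rate constants and reports.

Each channel's apparent rate constant is weighted by the equilibrium mole
fraction of its protonation state (k_f = f·k_app); the overall rate constant
is the sum of the weighted channel rates, and the branching ratio of channel
i is Γ_i = 100·k_i/k_overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .model import MediumSpec, ReactionPathway
from .screen import FeasibilityVerdict

__all__ = [
    "PathwayRate",
    "ScenarioResult",
    "weight_rate",
    "overall_rate",
    "branching_ratios",
    "compare_to_references",
    "load_reference_constants",
    "results_to_frame",
    "render_markdown",
    "render_json",
]


@dataclass
class PathwayRate:
    """One channel's kinetic record after diffusion correction and weighting."""

    pathway: ReactionPathway
    kappa_or_lambda: Optional[float]  # kappa for HAT/RAF, lambda for SET
    dG_activation: Optional[float]
    k_activation: Optional[float]
    k_diffusion: Optional[float]
    k_app: float
    mole_fraction: float
    k_weighted: float = field(init=False)
    branching_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mole_fraction <= 1.0):
            raise ValueError(f"mole_fraction must lie in [0,1], got {self.mole_fraction}")
        if self.k_app < 0:
            raise ValueError("k_app must be >= 0")
        self.k_weighted = weight_rate(self.k_app, self.mole_fraction)


@dataclass
class ScenarioResult:
    """All channels of one compound in one medium, plus the overall rate."""

    compound_id: str
    medium: MediumSpec
    pathway_rates: list[PathwayRate]
    excluded: list[FeasibilityVerdict] = field(default_factory=list)
    k_overall: float = field(init=False)

    def __post_init__(self) -> None:
        weighted = [pr.k_weighted for pr in self.pathway_rates]
        self.k_overall = overall_rate(weighted) if weighted else 0.0
        if self.k_overall > 0:
            for pr, pct in zip(self.pathway_rates, branching_ratios(weighted)):
                pr.branching_pct = pct


def weight_rate(k_app: float, mole_fraction: float) -> float:
    """k_f = f·k_app: weight a channel rate by its state's population."""
    if not (0.0 <= mole_fraction <= 1.0):
        raise ValueError(f"mole_fraction must lie in [0,1], got {mole_fraction}")
    return k_app * mole_fraction


def overall_rate(weighted_rates: Sequence[float]) -> float:
    """Sum of the weighted channel rate constants."""
    if len(weighted_rates) == 0:
        raise ValueError("need at least one weighted rate")
    if any(k < 0 for k in weighted_rates):
        raise ValueError("weighted rates must be >= 0")
    return float(sum(weighted_rates))


def branching_ratios(weighted_rates: Sequence[float]) -> list[float]:
    """Γ_i = 100·k_i/Σk, full precision (report layer rounds to integers)."""
    if len(weighted_rates) == 0:
        raise ValueError("need at least one weighted rate")
    total = overall_rate(weighted_rates)
    if total <= 0:
        raise ValueError("branching ratios undefined when all rates are zero")
    return [100.0 * k / total for k in weighted_rates]


def load_reference_constants() -> dict[str, dict[str, float]]:
    """Published per-medium overall rate constants of common antioxidants."""
    text = resources.files("radkin.data").joinpath(
        "reference_antioxidants.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {m: {k: float(v) for k, v in d.items()} for m, d in raw.items()}


def compare_to_references(k_overall: float, medium: str) -> pd.DataFrame:
    """Rank a computed overall rate constant against reference antioxidants.

    Returns a table sorted by decreasing rate with the computed value
    inserted under the name ``(computed)``.
    """
    refs = load_reference_constants()
    key = medium.replace("-", " ").strip().lower()
    if key not in refs:
        raise ValueError(
            f"no reference constants for medium {medium!r}; known: {sorted(refs)}"
        )
    rows = [{"antioxidant": n, "k_overall": v, "computed": False} for n, v in refs[key].items()]
    rows.append({"antioxidant": "(computed)", "k_overall": k_overall, "computed": True})
    frame = pd.DataFrame(rows).sort_values(
        "k_overall", ascending=False, kind="mergesort"
    )
    frame["rank"] = range(1, len(frame) + 1)
    return frame.reset_index(drop=True)


# --- rendering -----------------------------------------------------------

def _sig3(x: Optional[float]) -> str:
    """Three significant figures, scientific notation; half-even rounding."""
    if x is None:
        return ""
    return f"{x:.2e}"


def results_to_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Flat channel-level table, one row per retained pathway."""
    rows = []
    for res in results:
        for pr in res.pathway_rates:
            p = pr.pathway
            rows.append(
                {
                    "compound": res.compound_id,
                    "medium": res.medium.name,
                    "state": p.state_id,
                    "mechanism": p.mechanism.value,
                    "site": p.site or "",
                    "dG_reaction": p.dG_reaction,
                    "dG_activation": pr.dG_activation,
                    "kappa_or_lambda": pr.kappa_or_lambda,
                    "k_app": pr.k_app,
                    "mole_fraction": pr.mole_fraction,
                    "k_weighted": pr.k_weighted,
                    "branching_pct": pr.branching_pct,
                    "k_overall": res.k_overall,
                }
            )
    columns = [
        "compound", "medium", "state", "mechanism", "site", "dG_reaction",
        "dG_activation", "kappa_or_lambda", "k_app", "mole_fraction",
        "k_weighted", "branching_pct", "k_overall",
    ]
    return pd.DataFrame(rows, columns=columns)


def render_markdown(results: Iterable[ScenarioResult]) -> str:
    """Markdown tables in the style of a published kinetics table.

    Rates to 3 significant figures, mole fractions to 3 decimals, branching
    ratios rounded (half-even) to integers; footnotes mark the mole-fraction
    weighting and the SET λ column.
    """
    lines: list[str] = []
    for res in results:
        lines.append(f"### {res.compound_id} in {res.medium.name}")
        lines.append("")
        lines.append(
            "| Mechanism | Site | State | ΔG≠ | κ/λ ^c^ | k_app | f ^a^ | k_f ^b^ | Γ (%) |"
        )
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for pr in res.pathway_rates:
            p = pr.pathway
            gamma = "" if pr.branching_pct is None else f"{round(pr.branching_pct):d}"
            lines.append(
                f"| {p.mechanism.value} | {p.site or ''} | {p.state_id} "
                f"| {'' if pr.dG_activation is None else f'{pr.dG_activation:.1f}'} "
                f"| {'' if pr.kappa_or_lambda is None else f'{pr.kappa_or_lambda:.1f}'} "
                f"| {_sig3(pr.k_app)} | {pr.mole_fraction:.3f} "
                f"| {_sig3(pr.k_weighted)} | {gamma} |"
            )
        lines.append("")
        lines.append(f"k_overall = {_sig3(res.k_overall)} M⁻¹s⁻¹")
        if res.excluded:
            lines.append("")
            lines.append("Channels excluded by the thermodynamic screen:")
            for v in res.excluded:
                lines.append(f"- {v.pathway.label if v.pathway else '?'}: {v.reason}")
        lines.append("")
        lines.append(
            "^a^ mole fraction; ^b^ k_f = f·k_app; ^c^ tunneling correction κ "
            "(HAT/RAF) or reorganization energy λ in kcal/mol (SET)."
        )
        lines.append("")
    return "\n".join(lines)


def render_json(results: Iterable[ScenarioResult]) -> str:
    """Deterministic JSON export of scenario results (sorted keys)."""
    payload = []
    for res in results:
        payload.append(
            {
                "compound": res.compound_id,
                "medium": res.medium.name,
                "k_overall": res.k_overall,
                "pathways": [
                    {
                        "state": pr.pathway.state_id,
                        "mechanism": pr.pathway.mechanism.value,
                        "site": pr.pathway.site,
                        "dG_activation": pr.dG_activation,
                        "kappa_or_lambda": pr.kappa_or_lambda,
                        "k_app": pr.k_app,
                        "mole_fraction": pr.mole_fraction,
                        "k_weighted": pr.k_weighted,
                        "branching_pct": pr.branching_pct,
                    }
                    for pr in res.pathway_rates
                ],
                "excluded": [
                    {
                        "pathway": v.pathway.label if v.pathway else None,
                        "dG_reaction": v.dG_reaction,
                        "verdict": v.label.value,
                        "reason": v.reason,
                    }
                    for v in res.excluded
                ],
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True)
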