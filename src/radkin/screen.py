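"""Thermodynamic feasibility screen.

Channels with negative reaction Gibbs energy are favorable; slightly
endergonic ("almost isergonic") channels are kept for the kinetic study up to
a cutoff; strongly endergonic channels are excluded.  Excluded channels are
never silently dropped — the verdict record keeps the full screen visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .model import ReactionPathway

__all__ = [
    "FeasibilityLabel",
    "FeasibilityVerdict",
    "DEFAULT_BORDERLINE_CUTOFF",
    "classify_pathway",
    "screen_pathways",
    "verdicts_to_frame",
]

# kcal/mol; retains near-isergonic channels (reaction Gibbs energies of a few
# kcal/mol) while excluding channels tens of kcal/mol uphill
DEFAULT_BORDERLINE_CUTOFF = 5.0


class FeasibilityLabel(str, Enum):
    FAVORABLE = "favorable"
    BORDERLINE = "borderline"
    EXCLUDED = "excluded"


_STRICTNESS = {
    FeasibilityLabel.FAVORABLE: 0,
    FeasibilityLabel.BORDERLINE: 1,
    FeasibilityLabel.EXCLUDED: 2,
}


@dataclass(frozen=True)
class FeasibilityVerdict:
    pathway: Optional[ReactionPathway]
    dG_reaction: Optional[float]
    label: FeasibilityLabel
    retained_for_kinetics: bool
    reason: str

    @property
    def strictness(self) -> int:
        return _STRICTNESS[self.label]


def classify_pathway(
    dG_reaction: Optional[float],
    borderline_cutoff: float = DEFAULT_BORDERLINE_CUTOFF,
    pathway: Optional[ReactionPathway] = None,
) -> FeasibilityVerdict:
    """Classify one channel by its reaction Gibbs energy (kcal·mol⁻¹).

    dG < 0 → favorable; 0 ≤ dG ≤ cutoff → borderline (kinetically admissible
    despite being slightly endergonic); dG > cutoff → excluded.  A channel
    without a stated dG (already pre-screened upstream) is retained as
    favorable by assumption.
    """
    if borderline_cutoff < 0:
        raise ValueError(f"borderline_cutoff must be >= 0, got {borderline_cutoff}")
    if dG_reaction is None:
        return FeasibilityVerdict(
            pathway, None, FeasibilityLabel.FAVORABLE, True,
            "no reaction Gibbs energy stated; retained by assumption",
        )
    if dG_reaction < 0:
        label, retained = FeasibilityLabel.FAVORABLE, True
        reason = f"exergonic (dG = {dG_reaction:g} kcal/mol)"
    elif dG_reaction <= borderline_cutoff:
        label, retained = FeasibilityLabel.BORDERLINE, True
        reason = (
            f"almost isergonic (dG = {dG_reaction:g} <= cutoff "
            f"{borderline_cutoff:g} kcal/mol); kept for kinetics"
        )
    else:
        label, retained = FeasibilityLabel.EXCLUDED, False
        reason = (
            f"endergonic beyond cutoff (dG = {dG_reaction:g} > "
            f"{borderline_cutoff:g} kcal/mol)"
        )
    return FeasibilityVerdict(pathway, dG_reaction, label, retained, reason)


def screen_pathways(
    pathways: Iterable[ReactionPathway],
    borderline_cutoff: float = DEFAULT_BORDERLINE_CUTOFF,
) -> list[FeasibilityVerdict]:
    return [
        classify_pathway(p.dG_reaction, borderline_cutoff, pathway=p)
        for p in pathways
    ]


def verdicts_to_frame(verdicts: Iterable[FeasibilityVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        p = v.pathway
        rows.append(
            {
                "compound": p.compound_id if p else "",
                "state": p.state_id if p else "",
                "mechanism": p.mechanism.value if p else "",
                "site": (p.site or "") if p else "",
                "dG_reaction_kcal": v.dG_reaction,
                "verdict": v.label.value,
                "retained_for_kinetics": v.retained_for_kinetics,
                "reason": v.reason,
            }
        )
    return pd.DataFrame(rows)
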