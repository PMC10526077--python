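"""Energy unit parsing.

Config files must state units on every energy field; values are converted to
kcal·mol⁻¹ at parse time.  Conversions round-trip to 10 significant figures.
"""

from __future__ import annotations

__all__ = ["parse_energy", "format_energy", "KCAL_PER_UNIT"]

# 1 eV = e * N_A J/mol = 96485.33212... J/mol (CODATA-2018 exact e)
_EV_IN_J_PER_MOL = 1.602176634e-19 * 6.02214076e23

KCAL_PER_UNIT: dict[str, float] = {
    "kcal/mol": 1.0,
    "kcal·mol-1": 1.0,
    "cal/mol": 1e-3,
    "kj/mol": 1.0 / 4.184,
    "kj·mol-1": 1.0 / 4.184,
    "j/mol": 1.0 / 4184.0,
    "ev": _EV_IN_J_PER_MOL / 4184.0,
}


def parse_energy(value: object, field: str = "energy") -> float:
    """Parse an energy with mandatory units into kcal·mol⁻¹.

    Accepts a string like ``"14.2 kcal/mol"`` or a mapping
    ``{"value": 14.2, "units": "kcal/mol"}``.  Bare numbers are rejected so a
    kJ value can never silently masquerade as kcal.
    """
    if isinstance(value, str):
        parts = value.split()
        if len(parts) != 2:
            raise ValueError(
                f"{field}: expected '<number> <units>', got {value!r}"
            )
        number, unit = parts
    elif isinstance(value, dict):
        try:
            number, unit = value["value"], value["units"]
        except KeyError as exc:
            raise ValueError(f"{field}: mapping form needs 'value' and 'units'") from exc
    else:
        raise ValueError(
            f"{field}: energies must carry explicit units (got bare {value!r})"
        )
    key = str(unit).lower().replace("^", "").replace(" ", "")
    if key not in KCAL_PER_UNIT:
        raise ValueError(
            f"{field}: unknown energy unit {unit!r}; known: {sorted(KCAL_PER_UNIT)}"
        )
    return float(number) * KCAL_PER_UNIT[key]


def format_energy(value_kcal: float) -> str:
    """Serialize an internal kcal·mol⁻¹ energy back to the config dialect."""
    return f"{value_kcal:.10g} kcal/mol"
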