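"""Run-configuration parsing and serialization.

The config dialect is YAML with nested blocks; every energy field carries an
explicit unit string ("16.8 kcal/mol") and is normalized to kcal·mol⁻¹ at
parse time.  Unknown keys and dangling references are rejected with the
offending path named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import EckartBarrier, MediumSpec, ReactionPathway, SetParams, SpeciesState
from .screen import DEFAULT_BORDERLINE_CUTOFF
from .units import format_energy, parse_energy

__all__ = ["RunOptions", "CompoundSpec", "RunConfig", "ConfigError",
           "load_config", "loads_config", "dump_config", "dumps_config"]

_DEFAULT_VISCOSITY = {
    # handbook values at 298 K, Pa*s; overridable per medium block
    "water": 8.91e-4,
    "pentyl ethanoate": 8.62e-4,
}


class ConfigError(ValueError):
    """Schema violation, unknown key, or dangling reference in a config."""


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(block).__name__}")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass
class RunOptions:
    temperature: float = 298.15
    borderline_cutoff: float = DEFAULT_BORDERLINE_CUTOFF  # kcal/mol
    # "computed": rates from (dG_activation, kappa/Eckart, Marcus inputs);
    # "supplied": use per-pathway k_app values verbatim where present
    rate_source: str = "computed"

    def __post_init__(self) -> None:
        if self.rate_source not in {"computed", "supplied"}:
            raise ConfigError(
                f"options.rate_source must be 'computed' or 'supplied', got {self.rate_source!r}"
            )


@dataclass
class CompoundSpec:
    compound_id: str
    pka_values: tuple[float, ...]
    states: list[SpeciesState]
    pathways: list[ReactionPathway]


@dataclass
class RunConfig:
    compounds: list[CompoundSpec]
    media: list[MediumSpec]
    options: RunOptions = field(default_factory=RunOptions)
    title: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        for comp in self.compounds:
            state_ids = {s.state_id for s in comp.states}
            if len(state_ids) != len(comp.states):
                raise ConfigError(f"compounds[{comp.compound_id}]: duplicate state ids")
            for p in comp.pathways:
                if p.state_id not in state_ids:
                    raise ConfigError(
                        f"compounds[{comp.compound_id}]: pathway {p.label} references "
                        f"undeclared state {p.state_id!r}"
                    )


def _parse_medium(block: dict, path: str) -> MediumSpec:
    _check_keys(
        block,
        {"name", "aqueous", "temperature", "pH", "viscosity",
         "reactant_radii", "diffusion_override"},
        path,
    )
    if "name" not in block:
        raise ConfigError(f"{path}: missing 'name'")
    name = str(block["name"])
    viscosity = block.get("viscosity", _DEFAULT_VISCOSITY.get(name.lower(), 8.91e-4))
    radii = block.get("reactant_radii")
    try:
        return MediumSpec(
            name=name,
            aqueous=bool(block.get("aqueous", "pH" in block)),
            temperature=float(block.get("temperature", 298.15)),
            pH=None if block.get("pH") is None else float(block["pH"]),
            viscosity=float(viscosity),
            reactant_radii=None if radii is None else {str(k): float(v) for k, v in radii.items()},
            diffusion_override=(
                None if block.get("diffusion_override") is None
                else float(block["diffusion_override"])
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_state(block: dict, compound_id: str, path: str) -> SpeciesState:
    _check_keys(
        block,
        {"id", "net_charge", "deprotonation_count", "mole_fraction", "sites", "notes"},
        path,
    )
    if "id" not in block:
        raise ConfigError(f"{path}: missing 'id'")
    sites: dict[str, dict] = {}
    for site, desc in (block.get("sites") or {}).items():
        desc = dict(desc or {})
        if "proton_affinity" in desc and desc["proton_affinity"] is not None:
            desc["proton_affinity"] = parse_energy(
                desc["proton_affinity"], f"{path}.sites[{site}].proton_affinity"
            )
        sites[str(site)] = desc
    try:
        return SpeciesState(
            compound_id=compound_id,
            state_id=str(block["id"]),
            net_charge=int(block.get("net_charge", 0)),
            deprotonation_count=int(block.get("deprotonation_count", 0)),
            mole_fraction=(
                None if block.get("mole_fraction") is None
                else float(block["mole_fraction"])
            ),
            site_descriptors=sites,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_pathway(block: dict, compound_id: str, path: str) -> ReactionPathway:
    _check_keys(
        block,
        {"state", "mechanism", "site", "dG_reaction", "dG_activation",
         "symmetry_number", "kappa", "eckart", "set_params", "k_app", "notes"},
        path,
    )
    for req in ("state", "mechanism"):
        if req not in block:
            raise ConfigError(f"{path}: missing {req!r}")

    def energy(key: str) -> Optional[float]:
        return None if block.get(key) is None else parse_energy(block[key], f"{path}.{key}")

    eckart = None
    if block.get("eckart") is not None:
        eb = block["eckart"]
        _check_keys(eb, {"forward_barrier", "reverse_barrier", "imaginary_wavenumber"},
                    f"{path}.eckart")
        eckart = EckartBarrier(
            forward_barrier=parse_energy(eb["forward_barrier"], f"{path}.eckart.forward_barrier"),
            reverse_barrier=parse_energy(eb["reverse_barrier"], f"{path}.eckart.reverse_barrier"),
            imaginary_wavenumber=float(eb["imaginary_wavenumber"]),
        )
    set_params = None
    if block.get("set_params") is not None:
        sp = block["set_params"]
        _check_keys(sp, {"dG0_set", "lambda_reorg", "dE_set"}, f"{path}.set_params")
        if "dG0_set" not in sp:
            raise ConfigError(f"{path}.set_params: missing 'dG0_set'")
        set_params = SetParams(
            dG0_set=parse_energy(sp["dG0_set"], f"{path}.set_params.dG0_set"),
            lambda_reorg=(
                None if sp.get("lambda_reorg") is None
                else parse_energy(sp["lambda_reorg"], f"{path}.set_params.lambda_reorg")
            ),
            dE_set=(
                None if sp.get("dE_set") is None
                else parse_energy(sp["dE_set"], f"{path}.set_params.dE_set")
            ),
        )
    try:
        return ReactionPathway(
            compound_id=compound_id,
            state_id=str(block["state"]),
            mechanism=block["mechanism"],
            site=None if block.get("site") is None else str(block["site"]),
            dG_reaction=energy("dG_reaction"),
            dG_activation=energy("dG_activation"),
            symmetry_number=int(block.get("symmetry_number", 1)),
            kappa=None if block.get("kappa") is None else float(block["kappa"]),
            eckart=eckart,
            set_params=set_params,
            k_app_supplied=None if block.get("k_app") is None else float(block["k_app"]),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def loads_config(text: str) -> RunConfig:
    """Parse and validate a config document from a YAML string."""
    raw = yaml.safe_load(text)
    if raw is None or not isinstance(raw, dict):
        raise ConfigError("config: empty document or not a mapping; missing 'compounds'")
    _check_keys(raw, {"title", "provenance", "options", "media", "compounds"}, "config")
    if "compounds" not in raw:
        raise ConfigError("config: missing 'compounds'")
    if "media" not in raw:
        raise ConfigError("config: missing 'media'")

    opt_block = raw.get("options") or {}
    _check_keys(opt_block, {"temperature", "borderline_cutoff", "rate_source"}, "options")
    options = RunOptions(
        temperature=float(opt_block.get("temperature", 298.15)),
        borderline_cutoff=(
            DEFAULT_BORDERLINE_CUTOFF
            if opt_block.get("borderline_cutoff") is None
            else parse_energy(opt_block["borderline_cutoff"], "options.borderline_cutoff")
        ),
        rate_source=str(opt_block.get("rate_source", "computed")),
    )

    media = [
        _parse_medium(m, f"media[{i}]") for i, m in enumerate(raw["media"])
    ]
    compounds: list[CompoundSpec] = []
    for i, cb in enumerate(raw["compounds"]):
        path = f"compounds[{i}]"
        _check_keys(cb, {"id", "pka_values", "states", "pathways", "notes"}, path)
        if "id" not in cb:
            raise ConfigError(f"{path}: missing 'id'")
        cid = str(cb["id"])
        states = [
            _parse_state(sb, cid, f"{path}.states[{j}]")
            for j, sb in enumerate(cb.get("states") or [])
        ]
        if not states:
            raise ConfigError(f"{path}: at least one state is required")
        pathways = [
            _parse_pathway(pb, cid, f"{path}.pathways[{j}]")
            for j, pb in enumerate(cb.get("pathways") or [])
        ]
        compounds.append(
            CompoundSpec(
                compound_id=cid,
                pka_values=tuple(float(p) for p in (cb.get("pka_values") or [])),
                states=states,
                pathways=pathways,
            )
        )
    return RunConfig(
        compounds=compounds,
        media=media,
        options=options,
        title=str(raw.get("title", "")),
        provenance=str(raw.get("provenance", "")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return loads_config(p.read_text())


def dump_config(config: RunConfig) -> dict:
    """Serialize a RunConfig back to the plain-dict form of the dialect."""
    doc: dict = {"title": config.title, "provenance": config.provenance}
    doc["options"] = {
        "temperature": config.options.temperature,
        "borderline_cutoff": format_energy(config.options.borderline_cutoff),
        "rate_source": config.options.rate_source,
    }
    doc["media"] = []
    for m in config.media:
        mb: dict = {"name": m.name, "aqueous": m.aqueous,
                    "temperature": m.temperature, "viscosity": m.viscosity}
        if m.pH is not None:
            mb["pH"] = m.pH
        if m.reactant_radii is not None:
            mb["reactant_radii"] = dict(m.reactant_radii)
        if m.diffusion_override is not None:
            mb["diffusion_override"] = m.diffusion_override
        doc["media"].append(mb)
    doc["compounds"] = []
    for c in config.compounds:
        cb: dict = {"id": c.compound_id, "pka_values": list(c.pka_values),
                    "states": [], "pathways": []}
        for s in c.states:
            sb: dict = {"id": s.state_id, "net_charge": s.net_charge,
                        "deprotonation_count": s.deprotonation_count}
            if s.mole_fraction is not None:
                sb["mole_fraction"] = s.mole_fraction
            if s.site_descriptors:
                sb["sites"] = {
                    site: {
                        **{k: v for k, v in desc.items() if k != "proton_affinity"},
                        **(
                            {"proton_affinity": format_energy(desc["proton_affinity"])}
                            if desc.get("proton_affinity") is not None
                            else {}
                        ),
                    }
                    for site, desc in s.site_descriptors.items()
                }
            cb["states"].append(sb)
        for p in c.pathways:
            pb: dict = {"state": p.state_id, "mechanism": p.mechanism.value}
            if p.site is not None:
                pb["site"] = p.site
            if p.dG_reaction is not None:
                pb["dG_reaction"] = format_energy(p.dG_reaction)
            if p.dG_activation is not None:
                pb["dG_activation"] = format_energy(p.dG_activation)
            if p.symmetry_number != 1:
                pb["symmetry_number"] = p.symmetry_number
            if p.kappa is not None:
                pb["kappa"] = p.kappa
            if p.eckart is not None:
                pb["eckart"] = {
                    "forward_barrier": format_energy(p.eckart.forward_barrier),
                    "reverse_barrier": format_energy(p.eckart.reverse_barrier),
                    "imaginary_wavenumber": p.eckart.imaginary_wavenumber,
                }
            if p.set_params is not None:
                spb: dict = {"dG0_set": format_energy(p.set_params.dG0_set)}
                if p.set_params.lambda_reorg is not None:
                    spb["lambda_reorg"] = format_energy(p.set_params.lambda_reorg)
                if p.set_params.dE_set is not None:
                    spb["dE_set"] = format_energy(p.set_params.dE_set)
                pb["set_params"] = spb
            if p.k_app_supplied is not None:
                pb["k_app"] = p.k_app_supplied
            cb["pathways"].append(pb)
        doc["compounds"].append(cb)
    return doc


def dumps_config(config: RunConfig) -> str:
    return yaml.safe_dump(dump_config(config), sort_keys=False)
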