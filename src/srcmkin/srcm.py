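"""Assembly of the shipped SRCM network and its substrate scenarios.

The packaged structure file (``data/srcm_network.yaml``) fixes compartments,
species, reactions and rate-law shapes; numeric kinetic constants come from a
:class:`~srcmkin.synth.ParameterTable`.  The model spans an acidogen
(*Clostridium acetobutylicum*, compartment ``CAC``) that ferments glycine and
alanine to acetate, a shared medium, and an aceticlastic methanogen
(*Methanosarcina acetivorans*, ``MAC``) that converts acetate to methane.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError
from .network import (
    Compartment,
    KineticModel,
    RateLaw,
    RateLawKind,
    Reaction,
    Species,
    validate_model,
)

__all__ = [
    "SubstrateMode",
    "ScenarioSpec",
    "ModelCensus",
    "load_network_structure",
    "build_srcm_model",
    "model_census",
    "apply_scenario",
    "stickland_hydrogen_balance",
    "AMINO_ACID_SPECIES",
]

#: medium species carrying each gelatin-derived amino acid
AMINO_ACID_SPECIES = {"glycine": "gly_e", "alanine": "ala_e", "proline": "pro_e"}

#: net H2 produced by amino-acid oxidation per carbon mole of protein consumed
H2_OXIDATIVE_COEFFICIENT = 0.174
#: H2 consumed by amino-acid (Stickland acceptor) reduction per carbon mole
H2_REDUCTIVE_COEFFICIENT = 0.040


def stickland_hydrogen_balance(
    oxidative: float = H2_OXIDATIVE_COEFFICIENT,
    reductive: float = H2_REDUCTIVE_COEFFICIENT,
) -> float:
    """Net stoichiometric H2 coefficient of coupled Stickland fermentation.

    Oxidative deaminations release H2 while reductive deaminations consume
    it; the default per-carbon-mole coefficients give the theoretical net
    excess of 0.134 mol H2 per carbon mole of protein.
    """
    if oxidative < 0 or reductive < 0:
        raise ConfigurationError("per-carbon-mole H2 coefficients must be >= 0")
    return oxidative - reductive


class SubstrateMode(str, enum.Enum):
    GLYCINE = "GLYCINE"
    ALANINE = "ALANINE"
    PAIR = "PAIR"


@dataclass
class ScenarioSpec:
    """Amino-acid feed constraint applied to the medium boundary species.

    ``feed`` maps amino-acid names (glycine/alanine/proline) to clamped
    medium concentrations in mmol/ml.  Omitted entries default to the
    gelatin-hydrolysate composition of the selected mode.
    """

    substrate_mode: SubstrateMode = SubstrateMode.PAIR
    feed: dict[str, float] = field(default_factory=dict)
    clamp: bool = True

    def __post_init__(self):
        self.substrate_mode = SubstrateMode(self.substrate_mode)

    def resolved_feed(self) -> dict[str, float]:
        from .synth import gelatin_feed

        base = gelatin_feed(100.0)
        if self.substrate_mode is SubstrateMode.GLYCINE:
            feed = {"glycine": base["glycine"], "alanine": 0.0, "proline": 0.0}
        elif self.substrate_mode is SubstrateMode.ALANINE:
            feed = {"glycine": 0.0, "alanine": base["alanine"], "proline": 0.0}
        else:
            feed = dict(base)
        feed.update(self.feed)
        for name, value in feed.items():
            if name not in AMINO_ACID_SPECIES:
                raise ConfigurationError(f"unknown substrate {name!r}")
            if value < 0:
                raise ConfigurationError(f"feed for {name!r} must be >= 0")
        if self.substrate_mode is SubstrateMode.PAIR:
            if feed.get("glycine", 0.0) <= 0 or feed.get("alanine", 0.0) <= 0:
                raise ConfigurationError("PAIR scenario requires nonzero glycine and alanine")
        return feed


@dataclass
class ModelCensus:
    """Per-compartment counts of intracellular reactions, metabolites and
    membrane transport reactions (a transporter counts in both compartments
    it connects)."""

    reactions: dict[str, int]
    metabolites: dict[str, int]
    transport: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "reactions": dict(self.reactions),
            "metabolites": dict(self.metabolites),
            "transport": dict(self.transport),
        }


def load_network_structure() -> dict:
    """Parse the packaged SRCM network structure document."""
    ref = resources.files("srcmkin.data").joinpath("srcm_network.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _species_from_entry(entry: dict) -> Species:
    return Species(
        id=entry["id"],
        compartment=entry["compartment"],
        name=entry.get("name", ""),
        initial_concentration=float(entry.get("initial", 0.0)),
        charge=int(entry.get("charge", 0)),
        boundary=bool(entry.get("boundary", False)),
    )


def build_srcm_model(param_table, structure: dict | None = None) -> KineticModel:
    """Assemble and validate the SRCM :class:`KineticModel`.

    Parameters
    ----------
    param_table : ParameterTable
        Kinetic constants covering every reaction of the structure file
        (see :func:`srcmkin.synth.generate_parameter_table`); its initial
        concentrations, when present, override the structure defaults.
    """
    struct = structure or load_network_structure()
    compartments = [Compartment(c["id"], c.get("label", "")) for c in struct["compartments"]]
    species = [_species_from_entry(e) for e in struct["species"]]

    missing = [r["id"] for r in struct["reactions"] if r["id"] not in param_table.reactions()]
    if missing:
        raise ConfigurationError(
            "parameter table is missing rows for reactions: " + ", ".join(sorted(missing))
        )

    reactions = []
    for entry in struct["reactions"]:
        rid = entry["id"]
        kind = RateLawKind(entry["kind"])
        driving = list(entry.get("driving", []))
        if kind is RateLawKind.MICHAELIS_MENTEN:
            law = RateLaw(
                kind=kind,
                vmax=param_table.vmax_of(rid),
                km={sid: param_table.km_of(rid)[sid] for sid in driving},
                modifiers=tuple(entry.get("modifiers", [])),
            )
        else:
            exps = param_table.exponents_of(rid)
            law = RateLaw(
                kind=kind,
                k=param_table.k_of(rid),
                exponents={sid: exps.get(sid, 1.0) for sid in driving},
                modifiers=tuple(entry.get("modifiers", [])),
            )
        reactions.append(
            Reaction(
                id=rid,
                name=entry.get("name", ""),
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                rate_law=law,
                ec_number=entry.get("ec"),
                transporter_class=entry.get("transporter_class"),
            )
        )

    model = KineticModel(
        compartments,
        species,
        reactions,
        metadata={"name": struct.get("name", "SRCM"), "description": struct.get("description", "")},
    )
    for sid, value in param_table.initial_concentrations().items():
        if sid in model._sidx:
            model.get_species(sid).initial_concentration = float(value)
    report = validate_model(model)
    if not report.ok:
        raise ConfigurationError("assembled model is invalid: " + "; ".join(report))
    model.param_table = param_table
    return model


def model_census(model: KineticModel) -> ModelCensus:
    """Count intracellular reactions, owned metabolites and transporters."""
    comps = [c.id for c in model.compartments]
    reactions = {c: 0 for c in comps}
    metabolites = {c: 0 for c in comps}
    transport = {c: 0 for c in comps}
    for s in model.species:
        metabolites[s.compartment] += 1
    for r in model.reactions:
        touched = {model.get_species(sid).compartment for sid in r.stoichiometry}
        if r.is_transport:
            for c in touched:
                transport[c] += 1
        else:
            # an intracellular reaction lives in its (single) compartment
            for c in touched:
                reactions[c] += 1
    return ModelCensus(reactions, metabolites, transport)


def apply_scenario(model: KineticModel, scenario: ScenarioSpec) -> KineticModel:
    """Return a copy with medium amino-acid boundary species set per scenario."""
    out = model.copy()
    for name, value in scenario.resolved_feed().items():
        sid = AMINO_ACID_SPECIES[name]
        sp = out.get_species(sid)
        sp.initial_concentration = float(value)
        sp.boundary = bool(scenario.clamp)
    out.invalidate_caches()  # boundary pattern changed
    return out
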