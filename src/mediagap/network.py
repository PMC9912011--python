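"""Stoichiometric data model: metabolites, reactions, networks and media.

The package uses a deliberately small two-compartment convention
(cytosol ``c`` / extracellular ``e``), which is sufficient to express the
dichotomy between importing a compound (a transport reaction) and
synthesizing it (a biosynthesis pathway).  Metabolite ids carry their
compartment as a suffix (``ala_c``, ``ala_e``).

Sign conventions
----------------
* Stoichiometric coefficients are negative for consumed metabolites and
  positive for produced ones.
* An exchange reaction moves a single extracellular compound across the
  system boundary with coefficient -1; positive flux is secretion,
  negative flux is uptake.  A medium therefore acts by setting exchange
  lower bounds to ``-max_uptake``.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

COMPARTMENTS = ("c", "e")  # cytosol, extracellular

KIND_METABOLIC = "metabolic"
KIND_TRANSPORT = "transport"
KIND_EXCHANGE = "exchange"
KIND_BIOMASS = "biomass"
KIND_SINK = "sink"
REACTION_KINDS = (
    KIND_METABOLIC,
    KIND_TRANSPORT,
    KIND_EXCHANGE,
    KIND_BIOMASS,
    KIND_SINK,
)

#: default flux bound magnitude (mmol/gDW/h), the usual constraint-based
#: stand-in for "unconstrained"
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A compound in a fixed compartment."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for metabolite {self.id!r}"
            )


@dataclass
class Reaction:
    """A bounded reaction with signed stoichiometry.

    ``genome_encoded`` marks reactions that a genome could actually carry
    (enzymatic/transport steps); exchanges, the biomass pseudo-reaction
    and sinks are modelling artefacts and are never genome encoded.
    ``pathway_tag`` is a free-form label ("ala_biosynthesis",
    "aa_transport", "decoy", ...) used to classify gap-fill additions.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    kind: str = KIND_METABOLIC
    genome_encoded: bool = True
    pathway_tag: str = ""
    origin: str = "draft"

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r} for {self.id!r}")

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class MetabolicNetwork:
    """A stoichiometric network with a designated biomass reaction."""

    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_id: str = ""

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites={m.id: _copy.copy(m) for m in self.metabolites.values()},
            reactions={r.id: r.copy() for r in self.reactions.values()},
            biomass_id=self.biomass_id,
        )

    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        self.reactions[rxn.id] = rxn

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == KIND_EXCHANGE]

    def exchange_for(self, compound_id: str) -> Optional[Reaction]:
        """The exchange reaction moving ``compound_id``, if any."""
        for r in self.exchange_reactions():
            if compound_id in r.stoichiometry:
                return r
        return None

    def genome_encoded_ids(self) -> Set[str]:
        return {r.id for r in self.reactions.values() if r.genome_encoded}


@dataclass
class Medium:
    """Maximal uptake rates (mmol/gDW/h) per extracellular compound.

    Compounds not listed have uptake 0 (unavailable).
    """

    id: str
    uptake_limits: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, lim in self.uptake_limits.items():
            if lim < 0:
                raise ValueError(f"negative uptake limit for {cid!r} in medium {self.id!r}")

    def limit(self, compound_id: str) -> float:
        return self.uptake_limits.get(compound_id, 0.0)

    def is_superset_of(self, other: "Medium") -> bool:
        return all(self.limit(c) >= lim for c, lim in other.uptake_limits.items())


@dataclass
class BiomassComposition:
    """Stoichiometric demands of the biomass reaction.

    ``amino_acid_ids`` singles out the (cytosolic) amino-acid precursors
    whose producibility defines auxotrophy calls.
    """

    precursors: Dict[str, float]
    amino_acid_ids: List[str]

    def __post_init__(self) -> None:
        for aid in self.amino_acid_ids:
            if aid not in self.precursors:
                raise ValueError(f"amino acid {aid!r} missing from biomass precursors")
        for cid, demand in self.precursors.items():
            if demand <= 0:
                raise ValueError(f"non-positive biomass demand for {cid!r}")


def validate_network(network: MetabolicNetwork) -> List[str]:
    """Check structural invariants; returns human-readable violations.

    An empty list means the network is well formed.  Violations are
    returned rather than raised so that callers can report all problems
    at once.
    """
    violations: List[str] = []
    for mid, met in network.metabolites.items():
        if mid != met.id:
            violations.append(f"metabolite key {mid!r} does not match id {met.id!r}")
    n_biomass = 0
    for rid, rxn in network.reactions.items():
        if rid != rxn.id:
            violations.append(f"reaction key {rid!r} does not match id {rxn.id!r}")
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rid}: lower bound {rxn.lower_bound} exceeds upper bound {rxn.upper_bound}"
            )
        for mid in rxn.stoichiometry:
            if mid not in network.metabolites:
                violations.append(f"reaction {rid}: unknown metabolite {mid!r}")
        if rxn.kind == KIND_EXCHANGE:
            mets = [network.metabolites[m] for m in rxn.stoichiometry if m in network.metabolites]
            if len(rxn.stoichiometry) != 1:
                violations.append(
                    f"exchange reaction {rid} touches {len(rxn.stoichiometry)} metabolites, expected 1"
                )
            elif mets and mets[0].compartment != "e":
                violations.append(f"exchange reaction {rid} touches a non-extracellular metabolite")
        if rxn.kind == KIND_BIOMASS:
            n_biomass += 1
        if rxn.kind in (KIND_EXCHANGE, KIND_BIOMASS, KIND_SINK) and rxn.genome_encoded:
            violations.append(f"reaction {rid} of kind {rxn.kind} must not be genome encoded")
    if n_biomass > 1:
        violations.append(f"{n_biomass} biomass reactions present, at most 1 allowed")
    if network.biomass_id not in network.reactions:
        violations.append(f"missing biomass reaction {network.biomass_id!r}")
    return violations


def subnetwork(network: MetabolicNetwork, keep: Iterable[str]) -> MetabolicNetwork:
    """Restrict a network to a reaction subset and the metabolites they use.

    The biomass reaction must be retained; anything else may be dropped.
    """
    keep = set(keep)
    unknown = keep - set(network.reactions)
    if unknown:
        raise KeyError(f"unknown reaction ids in keep set: {sorted(unknown)[:5]}")
    if network.biomass_id not in keep:
        raise ValueError("biomass reaction must be kept in any subnetwork")
    sub = MetabolicNetwork(biomass_id=network.biomass_id)
    for rid in sorted(keep):
        rxn = network.reactions[rid].copy()
        sub.add_reaction(rxn)
        for mid in rxn.stoichiometry:
            if mid not in sub.metabolites:
                sub.add_metabolite(_copy.copy(network.metabolites[mid]))
    return sub


def extracellular_id(compound_id: str) -> str:
    """Map a cytosolic compound id to its extracellular counterpart."""
    if compound_id.endswith("_c"):
        return compound_id[:-2] + "_e"
    return compound_id
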