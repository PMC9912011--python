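"""Model and media I/O.

JSON is the native model format and round-trips every field bit-exactly.
SBML (Level 3, FBC flux bounds) is an interchange layer implemented on
top of COBRApy, so exported files are readable by any standard
constraint-based toolchain; import is best-effort and maps species,
reactions and bounds back onto the package's types.

Media files are tab-separated tables with a required header
``compound_id  name  max_uptake`` (a ``delimiter=','`` switch is
available for CSV-style files).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, Optional

from .network import (
    KIND_BIOMASS,
    KIND_EXCHANGE,
    KIND_SINK,
    Medium,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    validate_network,
)

_SBML_COMPARTMENTS = {"c": "cytosol", "e": "extracellular"}
_SBML_COMPARTMENTS_BACK = {v: k for k, v in _SBML_COMPARTMENTS.items()}
_SBML_COMPARTMENTS_BACK.update({"c": "c", "e": "e"})


def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in sorted(network.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
                "genome_encoded": r.genome_encoded,
                "pathway_tag": r.pathway_tag,
                "origin": r.origin,
            }
            for r in sorted(network.reactions.values(), key=lambda r: r.id)
        ],
        "biomass_id": network.biomass_id,
    }


def network_from_dict(data: dict) -> MetabolicNetwork:
    net = MetabolicNetwork(biomass_id=data["biomass_id"])
    for m in data["metabolites"]:
        if m["compartment"] not in ("c", "e"):
            raise ValueError(f"unknown compartment {m['compartment']!r} for {m['id']!r}")
        net.add_metabolite(Metabolite(m["id"], m.get("name", ""), m["compartment"]))
    for r in data["reactions"]:
        net.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry=dict(r["stoichiometry"]),
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                kind=r["kind"],
                genome_encoded=bool(r["genome_encoded"]),
                pathway_tag=r.get("pathway_tag", ""),
                origin=r.get("origin", "draft"),
            )
        )
    return net


def write_model(path: str | Path, network: MetabolicNetwork) -> Path:
    """Write a network; `.xml`/`.sbml` suffixes select SBML, else JSON."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return write_sbml(path, network)
    path.write_text(json.dumps(network_to_dict(network), indent=1, sort_keys=True))
    return path


def read_model(path: str | Path) -> MetabolicNetwork:
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: invalid model JSON at line {exc.lineno}: {exc.msg}") from exc
    return network_from_dict(data)


def to_cobra(network: MetabolicNetwork):
    """Convert to a COBRApy model (used for SBML export and cross-checks)."""
    import cobra

    model = cobra.Model("mediagap_model")
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name or m.id, compartment=m.compartment
        )
        for m in network.metabolites.values()
    }
    for comp, name in _SBML_COMPARTMENTS.items():
        model.compartments = {**model.compartments, comp: name}
    rxns = []
    for r in sorted(network.reactions.values(), key=lambda r: r.id):
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        cr.annotation["mediagap"] = json.dumps(
            {"kind": r.kind, "genome_encoded": r.genome_encoded, "pathway_tag": r.pathway_tag}
        )
        rxns.append(cr)
    model.add_reactions(rxns)
    if network.biomass_id in network.reactions:
        model.objective = network.biomass_id
    return model


def from_cobra(model) -> MetabolicNetwork:
    """Map a COBRApy model onto the package's network type.

    Reaction kinds are recovered from the package's own annotation when
    present, otherwise inferred (single extracellular metabolite =>
    exchange; objective => biomass).
    """
    net = MetabolicNetwork()
    for m in model.metabolites:
        comp = _SBML_COMPARTMENTS_BACK.get(m.compartment)
        if comp is None:
            raise ValueError(f"unknown compartment {m.compartment!r} for species {m.id!r}")
        net.add_metabolite(Metabolite(m.id, m.name or m.id, comp))
    objective_ids = {v.name for v in model.objective.variables}
    for r in model.reactions:
        meta = {}
        raw = r.annotation.get("mediagap")
        if raw:
            try:
                meta = json.loads(raw if isinstance(raw, str) else raw[0])
            except (json.JSONDecodeError, TypeError):
                meta = {}
        stoich = {m.id: coef for m, coef in r.metabolites.items()}
        kind = meta.get("kind")
        if kind is None:
            if len(stoich) == 1 and net.metabolites[next(iter(stoich))].compartment == "e":
                kind = KIND_EXCHANGE
            elif r.id in objective_ids:
                kind = KIND_BIOMASS
            else:
                kind = "metabolic"
        genome_encoded = meta.get(
            "genome_encoded", kind not in (KIND_EXCHANGE, KIND_BIOMASS, KIND_SINK)
        )
        net.add_reaction(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                kind=kind,
                genome_encoded=genome_encoded,
                pathway_tag=meta.get("pathway_tag", ""),
            )
        )
        if kind == KIND_BIOMASS:
            net.biomass_id = r.id
    return net


def write_sbml(path: str | Path, network: MetabolicNetwork) -> Path:
    from cobra.io import write_sbml_model

    path = Path(path)
    write_sbml_model(to_cobra(network), str(path))
    return path


def read_sbml(path: str | Path) -> MetabolicNetwork:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))


def write_media(path: str | Path, medium: Medium, delimiter: str = "\t") -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["compound_id", "name", "max_uptake"])
        for cid in sorted(medium.uptake_limits):
            writer.writerow([cid, cid, repr(medium.uptake_limits[cid])])
    return path


def read_media(
    path: str | Path, medium_id: Optional[str] = None, delimiter: str = "\t"
) -> Medium:
    """Read a medium table; compounds not listed have uptake 0."""
    path = Path(path)
    limits: Dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty media file, header row required")
        required = ["compound_id", "name", "max_uptake"]
        if [h.strip() for h in header[:3]] != required:
            raise ValueError(f"{path}: expected header {required}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            cid = row[0].strip()
            try:
                rate = float(row[2])
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed uptake rate in row {row}")
            if rate < 0:
                raise ValueError(f"{path}:{lineno}: negative uptake for {cid!r}")
            if cid in limits:
                raise ValueError(f"{path}:{lineno}: duplicate compound {cid!r}")
            limits[cid] = rate
    return Medium(id=medium_id or path.stem, uptake_limits=limits)
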