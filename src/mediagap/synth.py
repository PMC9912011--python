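"""Synthetic universe, template organism, media suite and MAG-like cohorts.

This module builds a deliberately small metabolic "world" with the same
causal structure as a real automated-reconstruction pipeline:

* a **universal database** holding every candidate reaction: a mineral
  base (NH4, Pi, SO4, H2O) with transporters, two lumped carbon
  catabolism routes (glucose and citrate) feeding a shared precursor
  pool plus an energy currency, and — for each amino acid — both a
  linear biosynthesis pathway of ``k`` genome-encoded steps *and* a
  transporter/exchange pair.  Because ``k >= 2``, importing an amino
  acid is always cheaper (1 reaction) than synthesizing it (k
  reactions): the engine of medium-dependent gap-fill bias.
* a **template organism**: every non-decoy genome-encoded reaction; it
  is prototrophic and grows on all four bundled media.
* **decoy reactions** on disconnected metabolites, used as simulated
  contamination; they can never contribute to biomass.
* a **four-medium suite** mirroring the two-minimal/two-rich design of
  automated reconstruction platforms.
* **degraded genome sampling**: per-reaction Bernoulli dropout at the
  completeness rate plus decoy contamination, emulating a cohort of
  metagenome-assembled genomes (MAGs) of one species with variable
  quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .gapfill import UniversalDatabase
from .network import (
    DEFAULT_BOUND,
    KIND_BIOMASS,
    KIND_EXCHANGE,
    KIND_METABOLIC,
    KIND_SINK,
    KIND_TRANSPORT,
    BiomassComposition,
    Medium,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    subnetwork,
)

#: the 20 proteinogenic amino acids (three-letter codes)
AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: amino acids whose first biosynthesis step also assimilates sulfate
_SULFUR_AAS = frozenset({"cys", "met"})

MINERALS = ("nh4", "pi", "so4", "h2o")
CARBON_SOURCES = ("glc", "cit")

#: genome-encoded core reactions besides the amino-acid machinery:
#: 4 mineral transporters + (transporter + catabolic reaction) per carbon source
CORE_GENOME_SIZE = len(MINERALS) + 2 * len(CARBON_SOURCES)

BIOMASS_ID = "BIOMASS"
#: ATP demand of the biomass reaction (mmol/gDW per gDW)
BIOMASS_ATP_DEMAND = 20.0

MEDIA_IDS = ("citrate_min", "glucose_min", "rich_defined", "rich_complex")

#: uptake limits (mmol/gDW/h): organic nutrients are limiting, minerals are not
UPTAKE_ORGANIC = 10.0
UPTAKE_MINERAL = 1000.0


@dataclass
class UniverseConfig:
    """Blueprint knobs for the synthetic universal database."""

    n_amino_acids: int = 20
    pathway_length: int = 3
    n_decoys: int = 40
    seed: int = 42

    def __post_init__(self) -> None:
        if not 1 <= self.n_amino_acids <= 20:
            raise ValueError("n_amino_acids must be in [1, 20]")
        if self.pathway_length < 2:
            # k >= 2 keeps a transporter strictly cheaper than a pathway
            raise ValueError("pathway_length must be at least 2")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")


@dataclass
class Universe:
    """A built universe: database, template genome, biomass, media."""

    database: UniversalDatabase
    template_ids: Set[str]
    biomass: BiomassComposition
    config: UniverseConfig

    @property
    def network(self) -> MetabolicNetwork:
        return self.database.network

    def amino_acids(self) -> Sequence[str]:
        return AMINO_ACIDS[: self.config.n_amino_acids]

    def template_network(self) -> MetabolicNetwork:
        """The complete (prototrophic) template organism."""
        keep = self.template_ids | {
            r.id
            for r in self.network.reactions.values()
            if not r.genome_encoded
        }
        return subnetwork(self.network, keep)


def template_size(config: UniverseConfig) -> int:
    """Genome-encoded template reaction count implied by the blueprint.

    Each amino acid contributes k pathway steps plus one transporter; the
    core contributes mineral transporters and two carbon routes.
    """
    return config.n_amino_acids * (config.pathway_length + 1) + CORE_GENOME_SIZE


def _exchange(cid: str) -> Reaction:
    return Reaction(
        id=f"EX_{cid}",
        stoichiometry={cid: -1.0},
        lower_bound=0.0,  # closed until a medium is applied
        upper_bound=DEFAULT_BOUND,
        kind=KIND_EXCHANGE,
        genome_encoded=False,
        pathway_tag="exchange",
    )


def build_universe(config: UniverseConfig | None = None) -> Universe:
    """Construct the universal database, template genome and biomass.

    The construction is fully deterministic given the config; the seed is
    carried along for provenance and cohort derivation only.
    """
    config = config or UniverseConfig()
    net = MetabolicNetwork(biomass_id=BIOMASS_ID)
    aas = AMINO_ACIDS[: config.n_amino_acids]

    def met(cid: str, name: str = "") -> None:
        comp = "e" if cid.endswith("_e") else "c"
        net.add_metabolite(Metabolite(cid, name or cid, comp))

    # mineral base and carbon sources, extracellular + cytosolic
    for base in MINERALS + CARBON_SOURCES:
        met(f"{base}_e")
        met(f"{base}_c")
        net.add_reaction(_exchange(f"{base}_e"))
    met("prec_c", "central precursor pool")
    met("atp_c", "energy currency")

    for base in MINERALS:
        net.add_reaction(
            Reaction(
                id=f"T_{base}",
                stoichiometry={f"{base}_e": -1.0, f"{base}_c": 1.0},
                lower_bound=0.0,
                kind=KIND_TRANSPORT,
                pathway_tag="mineral_transport",
            )
        )

    # lumped catabolism: route existence and relative yield are what matter
    carbon_yields = {"glc": (2.0, 10.0), "cit": (1.0, 6.0)}
    for src, (prec_yield, atp_yield) in carbon_yields.items():
        net.add_reaction(
            Reaction(
                id=f"T_{src}",
                stoichiometry={f"{src}_e": -1.0, f"{src}_c": 1.0},
                lower_bound=0.0,
                kind=KIND_TRANSPORT,
                pathway_tag=f"{src}_catabolism",
            )
        )
        net.add_reaction(
            Reaction(
                id=f"CAT_{src}",
                stoichiometry={
                    f"{src}_c": -1.0,
                    "h2o_c": -1.0,
                    "prec_c": prec_yield,
                    "atp_c": atp_yield,
                },
                lower_bound=0.0,
                kind=KIND_METABOLIC,
                pathway_tag=f"{src}_catabolism",
            )
        )

    # amino acids: linear k-step pathway AND transporter + exchange
    k = config.pathway_length
    for aa in aas:
        met(f"{aa}_e")
        met(f"{aa}_c")
        net.add_reaction(_exchange(f"{aa}_e"))
        net.add_reaction(
            Reaction(
                id=f"T_{aa}",
                stoichiometry={f"{aa}_e": -1.0, f"{aa}_c": 1.0},
                lower_bound=0.0,
                kind=KIND_TRANSPORT,
                pathway_tag="aa_transport",
            )
        )
        first_substrates = {"prec_c": -1.0, "nh4_c": -1.0, "atp_c": -1.0}
        if aa in _SULFUR_AAS:
            first_substrates["so4_c"] = -1.0
        for step in range(1, k + 1):
            product = f"{aa}_c" if step == k else f"{aa}_i{step}_c"
            if step < k:
                met(product, f"{aa} pathway intermediate {step}")
            substrate = dict(first_substrates) if step == 1 else {f"{aa}_i{step - 1}_c": -1.0}
            net.add_reaction(
                Reaction(
                    id=f"PWY_{aa}_{step}",
                    stoichiometry={**substrate, product: 1.0},
                    lower_bound=0.0,
                    kind=KIND_METABOLIC,
                    pathway_tag=f"{aa}_biosynthesis",
                )
            )

    # decoys: importers of disconnected compounds; their cytosolic side is
    # consumed by nothing, so they can never carry steady-state flux
    decoy_ids: Set[str] = set()
    for j in range(config.n_decoys):
        cid = f"dcy{j:02d}"
        met(f"{cid}_e")
        met(f"{cid}_c")
        net.add_reaction(_exchange(f"{cid}_e"))
        rid = f"DCY_{cid}"
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={f"{cid}_e": -1.0, f"{cid}_c": 1.0},
                lower_bound=0.0,
                kind=KIND_TRANSPORT,
                pathway_tag="decoy",
            )
        )
        decoy_ids.add(rid)

    precursors: Dict[str, float] = {f"{aa}_c": 1.0 for aa in aas}
    precursors["atp_c"] = BIOMASS_ATP_DEMAND
    precursors["pi_c"] = 1.0
    net.add_reaction(
        Reaction(
            id=BIOMASS_ID,
            stoichiometry={cid: -demand for cid, demand in precursors.items()},
            lower_bound=0.0,
            kind=KIND_BIOMASS,
            genome_encoded=False,
            pathway_tag="biomass",
        )
    )

    # overflow outlets: ATP hydrolysis (maintenance) and precursor-pool
    # overflow; without them excess energy/carbon would violate steady
    # state and artificially forbid growth.  Boundary pseudo-reactions,
    # never genome encoded, present in every draft.
    for cid, rid in (("atp_c", "DM_atp"), ("prec_c", "DM_prec")):
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={cid: -1.0},
                lower_bound=0.0,
                kind=KIND_SINK,
                genome_encoded=False,
                pathway_tag="maintenance",
            )
        )

    template = {
        r.id
        for r in net.reactions.values()
        if r.genome_encoded and r.id not in decoy_ids
    }
    assert len(template) == template_size(config)
    biomass = BiomassComposition(
        precursors=precursors, amino_acid_ids=[f"{aa}_c" for aa in aas]
    )
    return Universe(
        database=UniversalDatabase(network=net, decoy_ids=decoy_ids),
        template_ids=template,
        biomass=biomass,
        config=config,
    )


def build_media_suite(universe: Universe) -> Dict[str, Medium]:
    """The four bundled media.

    Two defined minimal media differing in carbon source; one defined
    rich medium (minimal base + both carbon sources + every amino acid);
    one complex rich medium that additionally supplies the decoy-pool
    nutrients.  Both rich media are compound-wise supersets of both
    minimal media, so moving from a minimal to a rich medium can only
    add metabolic options — the superset structure behind the
    monotonicity guarantees.
    """
    base = {f"{m}_e": UPTAKE_MINERAL for m in MINERALS}
    aas = universe.amino_acids()
    citrate_min = Medium("citrate_min", {**base, "cit_e": UPTAKE_ORGANIC})
    glucose_min = Medium("glucose_min", {**base, "glc_e": UPTAKE_ORGANIC})
    rich_defined = Medium(
        "rich_defined",
        {
            **base,
            "glc_e": UPTAKE_ORGANIC,
            "cit_e": UPTAKE_ORGANIC,
            **{f"{aa}_e": UPTAKE_ORGANIC for aa in aas},
        },
    )
    decoy_ext = sorted(
        cid
        for rid in universe.database.decoy_ids
        for cid in universe.network.reactions[rid].stoichiometry
        if cid.endswith("_e")
    )
    rich_complex = Medium(
        "rich_complex",
        {
            **rich_defined.uptake_limits,
            **{cid: UPTAKE_ORGANIC for cid in decoy_ext},
        },
    )
    return {
        "citrate_min": citrate_min,
        "glucose_min": glucose_min,
        "rich_defined": rich_defined,
        "rich_complex": rich_complex,
    }


@dataclass
class GenomeSample:
    """A degraded genome: retained template reactions plus contaminants."""

    model_id: str
    retained_ids: Set[str]
    contaminant_ids: Set[str]
    completeness: float
    contamination: float
    seed: int

    def __post_init__(self) -> None:
        if self.retained_ids & self.contaminant_ids:
            raise ValueError("retained and contaminant reaction sets overlap")


@dataclass
class CohortConfig:
    """Cohort-level degradation parameters.

    Defaults emulate a 106-genome MAG cohort of a single species with
    completeness uniform on [0.60, 1.00] and contamination uniform on
    [0, 0.055].
    """

    n_models: int = 106
    completeness_range: Tuple[float, float] = (0.60, 1.00)
    contamination_range: Tuple[float, float] = (0.0, 0.055)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("completeness_range must lie within [0, 1]")
        clo, chi = self.contamination_range
        if not (0.0 <= clo <= chi <= 1.0):
            raise ValueError("contamination_range must lie within [0, 1]")
        if self.n_models < 1:
            raise ValueError("n_models must be at least 1")


def sample_genome(
    universe: Universe,
    completeness: float,
    contamination: float,
    seed: int,
    model_id: str = "",
) -> GenomeSample:
    """Draw one degraded genome.

    Every genome-encoded template reaction is retained independently with
    probability ``completeness`` (reaction-level dropout — the desk-scale
    analogue of an incomplete genome bin).  ``round(contamination *
    template size)`` decoy reactions are added as foreign content.
    Exchanges, biomass and sinks are not genome derived and are never
    dropped; they are attached when the draft network is materialized.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    if contamination < 0.0:
        raise ValueError("contamination must be non-negative")
    rng = np.random.default_rng(seed)
    template = sorted(universe.template_ids)
    mask = rng.random(len(template)) < completeness
    retained = {rid for rid, keep in zip(template, mask) if keep}
    n_contaminants = int(round(contamination * len(template)))
    decoys = sorted(universe.database.decoy_ids)
    n_contaminants = min(n_contaminants, len(decoys))
    contaminants = set(
        rng.choice(decoys, size=n_contaminants, replace=False)
    ) if n_contaminants else set()
    return GenomeSample(
        model_id=model_id or f"mag_{seed}",
        retained_ids=retained,
        contaminant_ids={str(c) for c in contaminants},
        completeness=completeness,
        contamination=contamination,
        seed=seed,
    )


def sample_cohort(config: CohortConfig, universe: Universe) -> List[GenomeSample]:
    """Draw a cohort of degraded genomes, reproducibly from one master seed."""
    rng = np.random.default_rng(config.seed)
    samples: List[GenomeSample] = []
    width = len(str(config.n_models))
    for i in range(config.n_models):
        completeness = rng.uniform(*config.completeness_range)
        contamination = rng.uniform(*config.contamination_range)
        sub_seed = int(rng.integers(0, 2**31))
        samples.append(
            sample_genome(
                universe,
                completeness,
                contamination,
                seed=sub_seed,
                model_id=f"mag_{i:0{width}d}",
            )
        )
    return samples


def draft_network(universe: Universe, sample: GenomeSample) -> MetabolicNetwork:
    """Materialize the draft model of a degraded genome.

    Retained and contaminant reactions plus every non-genome-encoded
    reaction (exchanges, biomass, sinks) — mirroring automated platforms,
    where boundary pseudo-reactions are added by the reconstructor, not
    read off the genome.
    """
    boundary = {
        r.id for r in universe.network.reactions.values() if not r.genome_encoded
    }
    keep = sample.retained_ids | sample.contaminant_ids | boundary
    return subnetwork(universe.network, keep)


def cohort_manifest(samples: Sequence[GenomeSample]):
    """Cohort summary rows (model_id, completeness, contamination, ...)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model_id": s.model_id,
                "completeness": s.completeness,
                "contamination": s.contamination,
                "n_retained": len(s.retained_ids),
                "n_contaminants": len(s.contaminant_ids),
                "seed": s.seed,
            }
            for s in samples
        ]
    )
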