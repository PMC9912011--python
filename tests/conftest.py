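"""Shared fixtures: toy networks, the default universe, and media."""

import pytest

from mediagap import (
    Medium,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    UniverseConfig,
    build_media_suite,
    build_universe,
)
from mediagap.network import (
    KIND_BIOMASS,
    KIND_EXCHANGE,
    KIND_SINK,
    KIND_TRANSPORT,
)


def make_chain_network() -> MetabolicNetwork:
    """EX_a -> transport -> sink chain, plus a trivial biomass on a_c."""
    net = MetabolicNetwork(biomass_id="BIOMASS")
    net.add_metabolite(Metabolite("a_e", compartment="e"))
    net.add_metabolite(Metabolite("a_c", compartment="c"))
    net.add_reaction(
        Reaction(
            "EX_a_e", {"a_e": -1.0}, 0.0, 1000.0, KIND_EXCHANGE, genome_encoded=False
        )
    )
    net.add_reaction(
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0, KIND_TRANSPORT)
    )
    net.add_reaction(
        Reaction(
            "SINK_a", {"a_c": -1.0}, 0.0, 1000.0, KIND_SINK, genome_encoded=False
        )
    )
    net.add_reaction(
        Reaction(
            "BIOMASS", {"a_c": -1.0}, 0.0, 1000.0, KIND_BIOMASS, genome_encoded=False
        )
    )
    return net


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    return make_chain_network()


@pytest.fixture(scope="session")
def universe():
    """Default universe: 20 amino acids, 3-step pathways, 40 decoys."""
    return build_universe(UniverseConfig())


@pytest.fixture(scope="session")
def media(universe):
    return build_media_suite(universe)


@pytest.fixture(scope="session")
def template(universe):
    return universe.template_network()


@pytest.fixture(scope="session")
def small_universe():
    """Two amino acids, 3-step pathways, 3 decoys: brute-force territory."""
    return build_universe(UniverseConfig(n_amino_acids=2, pathway_length=3, n_decoys=3))


@pytest.fixture(scope="session")
def small_media(small_universe):
    return build_media_suite(small_universe)


@pytest.fixture(scope="session")
def small_template(small_universe):
    return small_universe.template_network()
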