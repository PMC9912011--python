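"""FBA engine: growth, producibility, and LP-level invariants.

The independent oracle for objective values is COBRApy (GLPK backend),
fed through the SBML-compatible converter — a completely separate LP
stack from the scipy/HiGHS path under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediagap import (
    Medium,
    apply_medium,
    can_grow,
    max_producibility,
    solve_fba,
    subnetwork,
)
from mediagap.fba import _get_system
from mediagap.io import to_cobra

MASS_BALANCE_TOL = 1e-9


def assert_mass_balanced(network, solution):
    """Every optimal solution must satisfy S v = 0 and its bounds."""
    system = _get_system(network)
    v = np.array([solution.fluxes[rid] for rid in system.reaction_ids])
    residual = np.abs(system.S @ v)
    assert residual.max() <= MASS_BALANCE_TOL


def test_chain_objective_is_uptake_limited(chain_network):
    sol = solve_fba(chain_network, Medium("m", {"a_e": 10.0}), "SINK_a")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
    assert_mass_balanced(chain_network, sol)


def test_closed_medium_gives_zero_biomass(template):
    sol = solve_fba(template, Medium("empty", {}), template.biomass_id)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


class TestApplyMedium:
    def test_empty_medium_closes_all_exchanges(self, template):
        out = apply_medium(template, Medium("empty", {}))
        assert all(r.lower_bound == 0.0 for r in out.exchange_reactions())

    def test_single_compound(self, template):
        out = apply_medium(template, Medium("glc", {"glc_e": 10.0}))
        for r in out.exchange_reactions():
            expected = -10.0 if "glc_e" in r.stoichiometry else 0.0
            assert r.lower_bound == expected
            assert r.upper_bound == 1000.0

    def test_rich_medium_opens_exactly_20_amino_acid_exchanges(
        self, universe, template, media
    ):
        out = apply_medium(template, media["rich_defined"])
        aa_exchanges = [
            r
            for r in out.exchange_reactions()
            if r.lower_bound < 0
            and next(iter(r.stoichiometry)) in {f"{aa}_e" for aa in universe.amino_acids()}
        ]
        assert len(aa_exchanges) == 20

    def test_non_exchange_reactions_untouched(self, template, media):
        out = apply_medium(template, media["glucose_min"])
        for rid, rxn in template.reactions.items():
            if rxn.kind != "exchange":
                assert out.reactions[rid].lower_bound == rxn.lower_bound
                assert out.reactions[rid].upper_bound == rxn.upper_bound


def test_template_growth_matches_cobra_oracle(template, media):
    """Objective values agree with an independent LP stack on all media."""
    for medium in media.values():
        ours = solve_fba(template, medium, template.biomass_id)
        cm = to_cobra(apply_medium(template, medium))
        theirs = cm.optimize()
        assert ours.status == "optimal" and theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(
            theirs.objective_value, rel=1e-6, abs=1e-6
        )
        assert ours.objective_value > 0
        assert_mass_balanced(template, ours)


class TestProducibility:
    def test_disconnected_compound_is_unproducible(self, universe, template, media):
        # decoy cytosolic compounds exist only in the universal network
        assert max_producibility(universe.network, media["glucose_min"], "dcy00_c") == 0.0

    def test_intact_pathway_produces_on_minimal(self, template, media):
        assert max_producibility(template, media["glucose_min"], "ala_c") > 0

    def test_transporter_only_equals_uptake_limit(self, universe, template, media):
        k = universe.config.pathway_length
        pathway = {f"PWY_ala_{s}" for s in range(1, k + 1)}
        transporter_only = subnetwork(template, set(template.reactions) - pathway)
        value = max_producibility(transporter_only, media["rich_defined"], "ala_c")
        assert value == pytest.approx(10.0, abs=1e-6)

    def test_unknown_compound_raises(self, template, media):
        with pytest.raises(KeyError, match="nonexistent"):
            max_producibility(template, media["glucose_min"], "nonexistent_c")


class TestMonotonicityAndScaling:
    def test_superset_medium_never_hurts(self, universe, template, media):
        pairs = [
            ("glucose_min", "rich_defined"),
            ("rich_defined", "rich_complex"),
            ("citrate_min", "rich_defined"),
        ]
        for small_id, big_id in pairs:
            small, big = media[small_id], media[big_id]
            assert big.is_superset_of(small)
            b_small = solve_fba(template, small, template.biomass_id).objective_value
            b_big = solve_fba(template, big, template.biomass_id).objective_value
            assert b_big >= b_small - 1e-9
            for compound in ("ala_c", "trp_c", "atp_c", "prec_c"):
                assert (
                    max_producibility(template, big, compound)
                    >= max_producibility(template, small, compound) - 1e-9
                )

    @given(factor=st.floats(min_value=1.0, max_value=2.0))
    @settings(max_examples=10, deadline=None)
    def test_scaling_uptakes_scales_biomass_at_most_linearly(self, factor):
        # positive homogeneity of the LP: biomass(f * M) <= f * biomass(M)
        from mediagap import UniverseConfig, build_media_suite, build_universe

        uni = build_universe(UniverseConfig(n_amino_acids=2, pathway_length=2, n_decoys=0))
        tpl = uni.template_network()
        m = build_media_suite(uni)["glucose_min"]
        scaled = Medium("scaled", {c: factor * v for c, v in m.uptake_limits.items()})
        base = solve_fba(tpl, m, tpl.biomass_id).objective_value
        grown = solve_fba(tpl, scaled, tpl.biomass_id).objective_value
        assert grown <= factor * base + 1e-6
        assert grown >= base - 1e-9


def test_can_grow_threshold(template, media):
    assert can_grow(template, media["glucose_min"], epsilon=1e-3)
    assert not can_grow(template, Medium("empty", {}), epsilon=1e-3)
    with pytest.raises(ValueError):
        can_grow(template, media["glucose_min"], epsilon=0.0)


def test_no_carbon_no_growth(template, media):
    carbon = {"T_glc", "CAT_glc", "T_cit", "CAT_cit"}
    crippled = subnetwork(template, set(template.reactions) - carbon)
    assert not can_grow(crippled, media["glucose_min"])
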