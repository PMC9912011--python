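"""Synthetic universe, media suite, and degraded-genome sampling."""

import numpy as np
import pytest
from scipy import stats

from mediagap import (
    CohortConfig,
    UniverseConfig,
    build_media_suite,
    build_universe,
    draft_network,
    precursor_auxotrophies,
    sample_cohort,
    sample_genome,
    solve_fba,
    subnetwork,
    template_size,
    validate_network,
)


class TestBuildUniverse:
    @pytest.mark.parametrize(
        "n_aa, k", [(20, 3), (1, 2), (5, 4), (20, 2)]
    )
    def test_template_size_matches_blueprint_formula(self, n_aa, k):
        cfg = UniverseConfig(n_amino_acids=n_aa, pathway_length=k, n_decoys=5)
        uni = build_universe(cfg)
        # k pathway steps + 1 transporter per amino acid, 8 core reactions
        assert len(uni.template_ids) == template_size(cfg) == n_aa * (k + 1) + 8

    def test_smallest_universe_grows_everywhere(self):
        uni = build_universe(UniverseConfig(n_amino_acids=1, pathway_length=2, n_decoys=0))
        tpl = uni.template_network()
        for medium in build_media_suite(uni).values():
            sol = solve_fba(tpl, medium, tpl.biomass_id)
            assert sol.objective_value > 1e-3

    def test_template_prototrophic_on_every_bundled_medium(
        self, universe, template, media
    ):
        for medium in media.values():
            assert precursor_auxotrophies(template, medium, universe.biomass).count == 0

    def test_decoys_are_inert(self, universe, template, media):
        with_decoys = subnetwork(
            universe.network,
            set(template.reactions) | universe.database.decoy_ids,
        )
        for medium in media.values():
            base = solve_fba(template, medium, template.biomass_id).objective_value
            loaded = solve_fba(with_decoys, medium, with_decoys.biomass_id).objective_value
            assert loaded == pytest.approx(base, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UniverseConfig(pathway_length=1)
        with pytest.raises(ValueError):
            UniverseConfig(n_amino_acids=0)


class TestMediaSuite:
    def test_minimal_media_contain_no_amino_acids(self, universe, media):
        aa_ext = {f"{aa}_e" for aa in universe.amino_acids()}
        for mid in ("citrate_min", "glucose_min"):
            assert not aa_ext & set(media[mid].uptake_limits)

    def test_rich_media_are_supersets(self, media):
        assert media["rich_defined"].is_superset_of(media["glucose_min"])
        assert media["rich_defined"].is_superset_of(media["citrate_min"])
        assert media["rich_complex"].is_superset_of(media["rich_defined"])

    def test_rich_complex_strictly_larger(self, media):
        assert len(media["rich_complex"].uptake_limits) > len(
            media["rich_defined"].uptake_limits
        )

    def test_minimal_media_differ_only_in_carbon_source(self, media):
        cit = set(media["citrate_min"].uptake_limits)
        glc = set(media["glucose_min"].uptake_limits)
        assert cit - glc == {"cit_e"}
        assert glc - cit == {"glc_e"}


class TestSampleGenome:
    def test_perfect_genome(self, universe):
        s = sample_genome(universe, completeness=1.0, contamination=0.0, seed=1)
        assert s.retained_ids == universe.template_ids
        assert s.contaminant_ids == set()

    def test_contaminant_count_rounding(self, universe):
        # round(0.05 * 88) = 4 decoy contaminants, deterministically
        s = sample_genome(universe, completeness=0.9, contamination=0.05, seed=3)
        assert len(s.contaminant_ids) == round(0.05 * len(universe.template_ids))
        assert s.contaminant_ids <= universe.database.decoy_ids

    def test_retention_rate_matches_binomial_expectation(self, universe):
        """Mean retained fraction over many seeds ~ completeness (binomial)."""
        completeness = 0.8
        n = len(universe.template_ids)
        draws = 1000
        fractions = [
            len(sample_genome(universe, completeness, 0.0, seed=s).retained_ids) / n
            for s in range(draws)
        ]
        se = np.sqrt(completeness * (1 - completeness) / (n * draws))
        assert abs(np.mean(fractions) - completeness) < 3 * se

    def test_reproducible_from_seed(self, universe):
        a = sample_genome(universe, 0.7, 0.03, seed=11)
        b = sample_genome(universe, 0.7, 0.03, seed=11)
        assert a.retained_ids == b.retained_ids
        assert a.contaminant_ids == b.contaminant_ids

    def test_draft_network_keeps_boundary_reactions(self, universe):
        s = sample_genome(universe, 0.6, 0.05, seed=5)
        draft = draft_network(universe, s)
        assert validate_network(draft) == []
        assert universe.network.biomass_id in draft.reactions
        for rxn in universe.network.reactions.values():
            if not rxn.genome_encoded:
                assert rxn.id in draft.reactions
        assert draft.genome_encoded_ids() == s.retained_ids | s.contaminant_ids


class TestSampleCohort:
    def test_default_cohort_shape_and_ranges(self, universe):
        cohort = sample_cohort(CohortConfig(seed=1), universe)
        assert len(cohort) == 106
        assert all(0.60 <= s.completeness <= 1.00 for s in cohort)
        assert all(0.0 <= s.contamination <= 0.055 for s in cohort)
        assert len({s.model_id for s in cohort}) == 106
        assert all(0 <= s.seed < 2**31 for s in cohort)

    def test_single_model(self, universe):
        assert len(sample_cohort(CohortConfig(n_models=1, seed=2), universe)) == 1

    def test_deterministic_for_fixed_master_seed(self, universe):
        a = sample_cohort(CohortConfig(n_models=20, seed=9), universe)
        b = sample_cohort(CohortConfig(n_models=20, seed=9), universe)
        assert [(s.retained_ids, s.contaminant_ids) for s in a] == [
            (s.retained_ids, s.contaminant_ids) for s in b
        ]

    def test_completeness_tracks_retained_size(self, universe):
        """Degradation monotonicity: dropout count follows completeness."""
        cohort = sample_cohort(CohortConfig(seed=4), universe)
        rho, _ = stats.spearmanr(
            [s.completeness for s in cohort],
            [len(s.retained_ids) for s in cohort],
        )
        assert rho > 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_models=0)
        with pytest.raises(ValueError):
            CohortConfig(completeness_range=(0.5, 1.2))
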