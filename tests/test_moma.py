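"""MOMA quadratic projection and genome-wide essentiality screening."""

import numpy as np
import pytest

from gemflux.bruteforce import bruteforce_moma
from gemflux.core import INF, MetabolicModel, Metabolite, Reaction, build_stoichiometric_matrix
from gemflux.fba import apply_condition, knockout_model, solve_fba
from gemflux.moma import (
    compare_essential_sets,
    essentiality_screen,
    moma,
    single_gene_deletion_moma,
)
from gemflux.synth import SyntheticSpec, make_random_network


def _line_model(upper=1.0):
    """EX_in <-> balance forces v_EX = -v_R: the feasible set is a line."""
    mets = [Metabolite("a", "a")]
    rxns = [
        Reaction(id="EX_in", stoichiometry={"a": -1.0}, reversible=True,
                 lower_bound=-1.0, upper_bound=0.0, is_exchange=True),
        Reaction(id="R", stoichiometry={"a": -1.0}, lower_bound=0.0, upper_bound=upper),
    ]
    return MetabolicModel(mets, rxns, objective_reaction_id="R")


def test_projection_onto_a_line_closed_form():
    """Wild type (−1, 1); cap R at 0.4 → mutant (−0.4, 0.4), distance √0.72."""
    wild = solve_fba(_line_model())
    assert wild.fluxes == {"EX_in": -1.0, "R": 1.0}
    sol = moma(_line_model(upper=0.4), wild, set())
    assert sol.ok
    assert sol.fluxes["R"] == pytest.approx(0.4, abs=1e-9)
    assert sol.distance == pytest.approx(np.sqrt(2 * 0.36), abs=1e-9)


def test_knockout_of_zero_flux_reactions_leaves_wild_type(toy, trophic_conditions):
    model, _ = toy
    constrained = apply_condition(model, trophic_conditions["autotrophic"])
    wild = solve_fba(constrained)
    assert wild.fluxes["HEX"] == pytest.approx(0.0, abs=1e-12)
    sol = moma(constrained, wild, {"gHex"})
    assert sol.distance == pytest.approx(0.0, abs=1e-9)
    assert sol.gr_rate_ko == pytest.approx(wild.objective_value, abs=1e-9)


def test_distance_zero_iff_wild_type_feasible_for_mutant(small_specs):
    for spec in small_specs[:4]:
        model, truth = make_random_network(spec)
        constrained = apply_condition(model, truth.conditions["default"])
        wild = solve_fba(constrained)
        for gene in sorted(constrained.genes):
            sol = moma(constrained, wild, {gene})
            if not sol.ok:
                continue
            mutant = knockout_model(constrained, {gene})
            wt_feasible = all(
                rxn.lower_bound - 1e-9 <= wild.fluxes[rxn.id] <= rxn.upper_bound + 1e-9
                for rxn in mutant.reactions
            )
            assert (sol.distance < 1e-6) == wt_feasible, (spec.seed, gene)


def test_qp_matches_face_enumeration_oracle(small_specs):
    worst = 0.0
    for spec in small_specs:
        model, truth = make_random_network(spec)
        constrained = apply_condition(model, truth.conditions["default"])
        wild = solve_fba(constrained)
        for gene in sorted(constrained.genes):
            mutant = knockout_model(constrained, {gene})
            sol = moma(constrained, wild, {gene})
            S, _, cols = build_stoichiometric_matrix(mutant)
            w = np.array([wild.fluxes[r] for r in cols])
            lb = np.array([max(r.lower_bound, -1e3) for r in mutant.reactions])
            ub = np.array([min(r.upper_bound, 1e3) for r in mutant.reactions])
            oracle = bruteforce_moma(S, w, lb, ub)
            if oracle is None:
                assert sol.status == "infeasible"
                continue
            v = np.array([sol.fluxes[r] for r in cols])
            worst = max(worst, float(np.abs(v - oracle).max()))
    assert worst <= 1e-6


def test_mutant_never_exceeds_wild_type_growth(toy, trophic_conditions):
    model, _ = toy
    for name in ("autotrophic", "mixotrophic"):
        report = essentiality_screen(model, trophic_conditions[name], method="moma")
        assert (report.table["grRateKO"] <= report.gr_rate_wt + 1e-8).all(), name


class TestEssentialityScreens:
    def test_toy_essential_sets_match_ground_truth(self, toy, trophic_conditions):
        """Growth-based (FBA) screening recovers the structural essential sets."""
        model, truth = toy
        for name in ("autotrophic", "mixotrophic"):
            report = essentiality_screen(model, trophic_conditions[name], method="fba")
            assert report.essential_genes == truth.essential_genes[name], name

    def test_moma_flags_at_least_the_structural_essentials(self, toy, trophic_conditions):
        """MOMA's grRateKO never exceeds the mutant's FBA optimum, so every
        growth-essential gene is also MOMA-essential; the converse can fail:
        projecting from a degenerate wasteful reference optimum may strand a
        rerouting-dependent mutant (here the cyclic-light gene) at zero
        growth even though re-optimization would rescue it."""
        model, truth = toy
        for name in ("autotrophic", "mixotrophic"):
            moma_report = essentiality_screen(model, trophic_conditions[name], method="moma")
            fba_report = essentiality_screen(model, trophic_conditions[name], method="fba")
            assert fba_report.essential_genes <= moma_report.essential_genes, name
            extra = moma_report.essential_genes - fba_report.essential_genes
            # every extra flag is adjustment-lethal, not growth-lethal
            for gene in extra:
                row = fba_report.table.set_index("gene").loc[gene]
                assert row["grRateKO"] > 1e-6 * row["grRateWT"], (name, gene)
            assert extra == {"gCyc"}, name  # deterministic under the pinned solver

    def test_calvin_genes_uniquely_autotrophic(self, toy, trophic_conditions):
        model, truth = toy
        auto = essentiality_screen(model, trophic_conditions["autotrophic"], method="fba")
        mixo = essentiality_screen(model, trophic_conditions["mixotrophic"], method="fba")
        common, auto_only, mixo_only = compare_essential_sets(auto, mixo)
        assert common == truth.essential_genes["autotrophic"] & truth.essential_genes["mixotrophic"]
        assert auto_only == {"gCfixA", "gCfixB"}  # carbon fixation: dispensable on glucose
        assert mixo_only == {"gHex"}

    def test_isoenzyme_pair_members_are_not_essential(self, toy, trophic_conditions):
        model, _ = toy
        for method in ("fba", "moma"):
            report = essentiality_screen(model, trophic_conditions["autotrophic"], method=method)
            assert {"gLight1", "gLight2", "gProtA", "gProtB"}.isdisjoint(
                report.essential_genes
            ), method

    @pytest.mark.parametrize("seed", range(6))
    def test_planted_sole_path_gene_is_the_only_essential(self, seed):
        model, truth = make_random_network(
            SyntheticSpec(seed=seed, n_metabolites=6, n_reactions=8,
                          features=frozenset({"sole_path_gene"}))
        )
        report = essentiality_screen(model, truth.conditions["default"], method="moma")
        assert report.essential_genes == {"g_sole"}

    def test_fba_and_moma_agree_on_structurally_blocked_knockouts(self, small_specs):
        for spec in small_specs[:4]:
            model, truth = make_random_network(spec)
            fba_report = essentiality_screen(model, truth.conditions["default"], method="fba")
            moma_report = essentiality_screen(model, truth.conditions["default"], method="moma")
            fba_blocked = set(
                fba_report.table.loc[fba_report.table["grRateKO"] < 1e-9, "gene"]
            )
            moma_blocked = set(
                moma_report.table.loc[moma_report.table["grRateKO"] < 1e-9, "gene"]
            )
            assert fba_blocked == moma_blocked, spec.seed

    def test_report_carries_the_reference_flux_vector(self, toy, trophic_conditions):
        model, _ = toy
        report = essentiality_screen(model, trophic_conditions["autotrophic"], method="moma")
        assert report.wild_type_fluxes["BIOMASS"] == pytest.approx(report.gr_rate_wt)

    def test_mismatched_universes_rejected(self, toy, trophic_conditions):
        import pandas as pd

        model, _ = toy
        report = essentiality_screen(model, trophic_conditions["autotrophic"], method="fba")
        other = type(report)(
            condition="x", method="fba", gr_rate_wt=1.0, wild_type_fluxes={},
            table=pd.DataFrame({"gene": ["zz"], "grRateKO": [0.0], "grRateWT": [1.0],
                                "grRatio": [0.0], "essential": [True], "status": ["optimal"]}),
        )
        with pytest.raises(ValueError):
            compare_essential_sets(report, other)


def test_infeasible_mutant_reports_zero_growth(toy, trophic_conditions):
    model, _ = toy
    sol = single_gene_deletion_moma(model, "gHex", trophic_conditions["mixotrophic"])
    assert sol.status == "infeasible" and sol.gr_rate_ko == 0.0
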