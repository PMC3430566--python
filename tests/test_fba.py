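"""FBA engine: optima vs analytic/enumeration oracles, knockouts, invariants."""

import numpy as np
import pytest

from gemflux.bruteforce import bruteforce_fba
from gemflux.fba import (
    ObjectiveSpec,
    active_reactions,
    apply_condition,
    genes_to_disabled_reactions,
    knockout_model,
    simulate_growth_conditions,
    single_gene_deletion_fba,
    solve_fba,
    steady_state_residual,
)
from gemflux.fva import fva
from gemflux.synth import SyntheticSpec, make_random_network


def _growth(model, condition):
    return solve_fba(apply_condition(model, condition))


class TestToyPhototrophGrowth:
    def test_analytic_growth_rates(self, toy, trophic_conditions):
        model, truth = toy
        for name, condition in trophic_conditions.items():
            sol = _growth(model, condition)
            assert sol.ok, name
            assert sol.objective_value == pytest.approx(truth.growth[name], abs=1e-8), name

    def test_zero_photon_means_zero_growth(self, toy, trophic_conditions):
        model, _ = toy
        dark = trophic_conditions["autotrophic"].override(photon=(0.0, 0.0))
        sol = _growth(model, dark)
        # the fixed bicarbonate load still drains through carbonic anhydrase
        assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_growth_table_reports_infeasible_as_zero(self, toy, trophic_conditions):
        model, _ = toy
        table = simulate_growth_conditions(model, list(trophic_conditions.values()))
        assert list(table["condition"]) == ["autotrophic", "heterotrophic", "mixotrophic"]
        assert (table["growth_rate"] >= 0).all()
        assert table.loc[table["condition"] == "heterotrophic", "growth_rate"].item() == 0.0

    def test_no_conditions_gives_empty_table(self, toy):
        model, _ = toy
        assert simulate_growth_conditions(model, []).empty


class TestHexKnockout:
    """Deleting the sole glucose-entry gene reverts mixotrophy to autotrophy."""

    def test_fixed_glucose_makes_the_mutant_infeasible(self, toy, trophic_conditions):
        model, _ = toy
        sol = single_gene_deletion_fba(model, "gHex", trophic_conditions["mixotrophic"])
        assert sol.status == "infeasible"

    def test_glucose_as_availability_reverts_to_autotrophic_rate(self, toy, trophic_conditions):
        model, truth = toy
        relaxed = trophic_conditions["mixotrophic"].override(glc=(0.0, 0.017))
        sol = single_gene_deletion_fba(model, "gHex", relaxed)
        assert sol.objective_value == pytest.approx(
            truth.extras["hex_ko_mixotrophic_available"], abs=1e-8
        )

    def test_knockout_of_zero_flux_gene_changes_nothing(self, toy, trophic_conditions):
        model, truth = toy
        # glucose is closed autotrophically, so the hexokinase carries no flux
        sol = single_gene_deletion_fba(model, "gHex", trophic_conditions["autotrophic"])
        assert sol.objective_value == pytest.approx(truth.growth["autotrophic"], abs=1e-10)


def test_lp_matches_vertex_enumeration_oracle(small_specs):
    for spec in small_specs:
        model, truth = make_random_network(spec)
        constrained = apply_condition(model, truth.conditions["default"])
        sol = solve_fba(constrained)
        oracle, _ = bruteforce_fba(constrained, box_cap=100.0)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8), spec
        assert sol.objective_value == pytest.approx(truth.growth["default"], abs=1e-8), spec


def test_steady_state_residual_on_every_reported_optimum(toy, trophic_conditions, small_specs):
    model, _ = toy
    problems = [apply_condition(model, c) for c in trophic_conditions.values()]
    for spec in small_specs[:4]:
        m, t = make_random_network(spec)
        problems.append(apply_condition(m, t.conditions["default"]))
    for problem in problems:
        sol = solve_fba(problem)
        assert sol.ok
        v_scale = max(1.0, max(abs(v) for v in sol.fluxes.values()))
        assert steady_state_residual(problem, sol) <= 1e-9 * v_scale
        for rxn in problem.reactions:
            v = sol.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9


def test_relaxing_an_uptake_never_decreases_growth(toy, trophic_conditions):
    model, _ = toy
    base = trophic_conditions["autotrophic"]
    previous = 0.0
    for cap in [0.0, 0.05, 0.1, 0.2, 0.5]:
        sol = _growth(model, base.override(hco3=(0.0, cap)))
        assert sol.objective_value >= previous - 1e-10
        previous = sol.objective_value


def test_infeasible_and_unbounded_are_reported_not_raised(toy, trophic_conditions):
    model, _ = toy
    # forced uptake of a substrate with every outlet closed is infeasible
    impossible = trophic_conditions["heterotrophic"].override(glc=(0.017, 0.017), hco3=(0.2, 0.2))
    constrained = apply_condition(model, impossible)
    constrained = knockout_model(constrained, {"gHex"})
    sol = solve_fba(constrained)
    assert sol.status == "infeasible" and not sol.ok
    # maximizing an exchange that can secrete freely is unbounded
    unbounded = solve_fba(
        apply_condition(model, trophic_conditions["autotrophic"]),
        ObjectiveSpec({"ATPASE": 1.0}),
    )
    assert unbounded.status in ("unbounded", "optimal")  # photon cap may bind


class TestGeneToReactionMapping:
    @pytest.mark.parametrize(
        "knocked, disabled",
        [
            ({"gCfixA"}, {"CFIX"}),       # complex: one subunit suffices to kill
            ({"gLight1"}, set()),          # isoenzyme partner keeps it alive
            ({"gLight1", "gLight2"}, {"LIGHT_LINEAR"}),
            ({"gHex", "gChl"}, {"HEX", "CHL_SYN"}),
        ],
    )
    def test_and_or_semantics(self, toy, knocked, disabled):
        model, _ = toy
        assert genes_to_disabled_reactions(model, knocked) == disabled

    def test_empty_gpr_reactions_never_disabled(self, toy):
        model, _ = toy
        disabled = genes_to_disabled_reactions(model, set(model.genes))
        assert "BIOMASS" not in disabled and "ATPASE" not in disabled

    def test_unknown_gene_raises(self, toy):
        model, _ = toy
        with pytest.raises(KeyError):
            genes_to_disabled_reactions(model, {"gGhost"})

    def test_agreement_with_exhaustive_truth_tables(self):
        model, _ = make_random_network(
            SyntheticSpec(seed=11, gpr_style="complexes_and_isoenzymes")
        )
        genes = sorted(model.genes)
        for mask in range(2 ** len(genes)):
            knocked = {g for i, g in enumerate(genes) if mask >> i & 1}
            disabled = genes_to_disabled_reactions(model, knocked)
            for rxn in model.reactions:
                expected = not rxn.gpr.is_empty and not rxn.gpr.evaluate(frozenset(knocked))
                assert (rxn.id in disabled) == expected


def test_active_reactions_thresholding():
    from gemflux.fba import FluxSolution

    sol = FluxSolution(status="optimal", objective_value=0.5,
                       fluxes={"a": 1e-12, "b": 0.5, "c": 0.0})
    assert active_reactions(sol, epsilon=1e-9) == {"b"}
    with pytest.raises(ValueError):
        active_reactions(FluxSolution(status="infeasible", objective_value=float("nan")))
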