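"""Stoichiometric matrix assembly, topology, biomass assembly, statistics."""

import numpy as np
import pytest

from gemflux.core import (
    BiomassComposition,
    Compartment,
    MacromoleculeClass,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    INF,
    assemble_biomass_reaction,
    build_stoichiometric_matrix,
    check_elemental_balance,
    find_dead_end_metabolites,
    metabolite_connectivity,
    model_statistics,
    validate_model,
)
from gemflux.synth import SyntheticSpec, make_random_network


def _chain_model(with_exchange_for=("A",)):
    """A -> B -> C with exchanges for the named metabolites."""
    mets = [Metabolite(m, m) for m in "ABC"]
    rxns = [
        Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}),
        Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0}),
    ]
    for m in with_exchange_for:
        rxns.append(
            Reaction(
                id=f"EX_{m}", stoichiometry={m: -1.0}, reversible=True,
                lower_bound=-INF, upper_bound=INF, is_exchange=True,
            )
        )
    return MetabolicModel(mets, rxns, objective_reaction_id="R2")


def test_matrix_column_is_signed_stoichiometry():
    model = _chain_model()
    S, rows, cols = build_stoichiometric_matrix(model)
    j = cols.index("R1")
    assert S[rows.index("A"), j] == -1.0
    assert S[rows.index("B"), j] == 1.0
    assert S[rows.index("C"), j] == 0.0


def test_boundary_metabolites_are_not_rows():
    mets = [Metabolite("x", "x"), Metabolite("xb", "xb", Compartment.BOUNDARY)]
    rxns = [Reaction(id="EX_x", stoichiometry={"x": -1.0, "xb": 1.0}, is_exchange=True)]
    model = MetabolicModel(mets, rxns, objective_reaction_id="EX_x")
    S, rows, _ = build_stoichiometric_matrix(model)
    assert rows == ["x"] and S.shape == (1, 1)


def test_unknown_metabolite_is_a_structural_error():
    model = _chain_model()
    model.reactions.append(Reaction(id="bad", stoichiometry={"ghost": 1.0}))
    with pytest.raises(ModelStructureError, match="bad"):
        build_stoichiometric_matrix(model)


@pytest.mark.parametrize("seed", range(5))
def test_matrix_matches_independent_per_reaction_assembly(seed):
    model, _ = make_random_network(SyntheticSpec(seed=seed))
    S, rows, cols = build_stoichiometric_matrix(model)
    # brute-force oracle: fill entry by entry from scratch
    expected = np.zeros_like(S)
    for j, rxn_id in enumerate(cols):
        for met_id, coeff in model.reaction(rxn_id).stoichiometry.items():
            if met_id in rows:
                expected[rows.index(met_id), j] = coeff
    assert np.array_equal(S, expected)


@pytest.mark.parametrize("seed", range(5))
def test_connectivity_equals_nonzero_row_count(seed):
    model, _ = make_random_network(SyntheticSpec(seed=seed))
    S, rows, _ = build_stoichiometric_matrix(model)
    conn = metabolite_connectivity(model)
    for i, met_id in enumerate(rows):
        assert conn[met_id] == int(np.count_nonzero(S[i]))


def test_connectivity_of_absent_metabolite_is_zero():
    model = _chain_model()
    model.metabolites.append(Metabolite("unused", "unused"))
    model = MetabolicModel(model.metabolites, model.reactions, "R2")
    assert metabolite_connectivity(model)["unused"] == 0


def test_dead_end_chain():
    # A -> B -> C, exchange only for A: C is produced but never consumed
    assert find_dead_end_metabolites(_chain_model(("A",))) == {"C"}
    assert find_dead_end_metabolites(_chain_model(("A", "C"))) == set()


def test_reversible_reaction_is_producer_and_consumer():
    mets = [Metabolite(m, m) for m in "AB"]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, reversible=True,
                 lower_bound=-INF, upper_bound=INF, is_exchange=True),
        Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0}, reversible=True,
                 lower_bound=-INF, upper_bound=INF),
    ]
    model = MetabolicModel(mets, rxns, objective_reaction_id="R")
    assert find_dead_end_metabolites(model) == set()


@pytest.mark.parametrize("seed", range(8))
def test_planted_orphan_is_the_only_dead_end(seed):
    model, truth = make_random_network(
        SyntheticSpec(seed=seed, n_metabolites=7, n_reactions=9,
                      features=frozenset({"orphan_metabolite"}))
    )
    assert find_dead_end_metabolites(model) == truth.dead_ends == {"orphan"}


class TestBiomassAssembly:
    def composition(self):
        return BiomassComposition(
            classes={
                "protein": MacromoleculeClass(0.68, 0.8404, {"alanine": 0.1010, "glycine": 0.0860}),
                "carbohydrate": MacromoleculeClass(0.32, 0.1230, {"glycogen": 0.0430}),
            }
        )

    def test_component_coefficient_is_class_times_ratio(self):
        rxn = assemble_biomass_reaction(self.composition())
        assert rxn.stoichiometry["alanine"] == pytest.approx(-(0.8404 * 0.1010))
        assert rxn.stoichiometry["glycogen"] == pytest.approx(-(0.1230 * 0.0430))

    def test_all_substrates_negative_and_biomass_produced(self):
        rxn = assemble_biomass_reaction(self.composition())
        assert rxn.stoichiometry["biomass"] == 1.0
        assert all(c < 0 for m, c in rxn.stoichiometry.items() if m != "biomass")
        assert not rxn.reversible and rxn.gpr.is_empty

    def test_empty_composition_is_an_error(self):
        with pytest.raises(ValueError):
            assemble_biomass_reaction(BiomassComposition(classes={}))

    def test_mass_fractions_must_sum_to_one(self):
        bad = BiomassComposition(
            classes={"protein": MacromoleculeClass(0.5, 1.0, {"x": 1.0})}
        )
        with pytest.raises(ValueError, match="mass fractions"):
            bad.validate()


def test_statistics_partition_identities(toy):
    model, _ = toy
    stats = model_statistics(model)
    assert stats.n_internal + stats.n_exchange == stats.n_reactions
    assert stats.n_gene_associated + stats.n_orphan == stats.n_internal
    assert stats.n_reversible_internal + stats.n_irreversible_internal == stats.n_internal
    assert stats.n_genes == len(model.genes)


@pytest.mark.parametrize("seed", range(5))
def test_statistics_identities_on_random_models(seed):
    model, _ = make_random_network(SyntheticSpec(seed=seed, gpr_style="complexes_and_isoenzymes"))
    stats = model_statistics(model)
    assert stats.n_internal + stats.n_exchange == stats.n_reactions
    assert stats.n_gene_associated + stats.n_orphan == stats.n_internal


def test_statistics_of_empty_model():
    stats = model_statistics(MetabolicModel([], [], objective_reaction_id=""))
    assert all(v == 0 for v in vars(stats).values())


class TestValidation:
    def test_generated_models_are_clean(self, toy):
        model, _ = toy
        assert validate_model(model, declared_genes=model.genes).ok

    def test_bound_violation_reported(self):
        model = _chain_model()
        model.reactions[0] = Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                                      lower_bound=2.0, upper_bound=1.0)
        report = validate_model(model)
        assert any("lower_bound" in issue for issue in report.issues)

    def test_undeclared_gpr_gene_reported(self):
        model = _chain_model()
        from gemflux.gpr import parse_gpr

        model.reactions[0] = Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                                      gpr=parse_gpr("gX"))
        report = validate_model(model, declared_genes={"gY"})
        assert any("gX" in issue for issue in report.issues)
        # validation reports, it never raises
        assert isinstance(report.issues, list)

    def test_missing_objective_reported(self):
        model = MetabolicModel([Metabolite("A", "A")], [], objective_reaction_id="")
        assert not validate_model(model).ok


def test_elemental_balance_advisory():
    mets = [
        Metabolite("glc", "glucose", formula={"C": 6, "H": 12, "O": 6}),
        Metabolite("c3", "triose", formula={"C": 3, "H": 6, "O": 3}),
        Metabolite("x", "no formula"),
    ]
    balanced = Reaction(id="split", stoichiometry={"glc": -1.0, "c3": 2.0})
    missing = Reaction(id="m", stoichiometry={"glc": -1.0, "x": 1.0})
    model = MetabolicModel(mets, [balanced, missing], objective_reaction_id="split")
    net = check_elemental_balance(model, balanced)
    assert net == {"C": 0.0, "H": 0.0, "O": 0.0}
    assert check_elemental_balance(model, missing) is None
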