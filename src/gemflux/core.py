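"""Domain types for constraint-based metabolic models.

The central object is :class:`MetabolicModel`: metabolites (rows of the
stoichiometric matrix S), reactions (columns), boolean gene associations,
and a biomass objective.  This module also carries the structural analyses
that need no solver: S assembly, metabolite connectivity, dead-end
detection, biomass assembly from a macromolecular composition, model
statistics, and validation.

Conventions
-----------
* Stoichiometric coefficients are signed: negative = consumed,
  positive = produced.
* Fluxes are in mmol/mmol dry cell/h; the biomass flux is in 1/h.
* Irreversible reactions have ``lower_bound >= 0``; reversible reactions
  may carry flux of either sign.
* ``boundary`` metabolites exist only to open the system (the partners of
  exchange reactions); they are excluded from the steady-state balance and
  hence from the rows of S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .gpr import GPRExpression

INF = math.inf


class Compartment(str, Enum):
    CYTOSOL = "cytosol"
    EXTRACELLULAR = "extracellular"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.CYTOSOL
    formula: Mapping[str, int] | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with bounds and a gene rule."""

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = INF
    gpr: GPRExpression = field(default_factory=GPRExpression.empty)
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("reaction id must be non-empty")

    @property
    def substrates(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class ModelStructureError(ValueError):
    """A reaction references an unknown metabolite, or similar defects."""


@dataclass
class MetabolicModel:
    """Metabolites + reactions + genes + a biomass objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction_id: str = ""
    id: str = "model"

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def genes(self) -> set[str]:
        """Union of GPR leaves over all reactions."""
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return out

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_exchange]

    def balanced_metabolites(self) -> list[Metabolite]:
        """Metabolites subject to the steady-state constraint (non-boundary)."""
        return [m for m in self.metabolites if m.compartment is not Compartment.BOUNDARY]

    def with_reactions(self, reactions: list[Reaction]) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=reactions,
            objective_reaction_id=self.objective_reaction_id,
            id=self.id,
        )

    def copy(self) -> "MetabolicModel":
        return self.with_reactions(list(self.reactions))


@dataclass(frozen=True)
class MacromoleculeClass:
    """One row-group of a biomass composition table."""

    mass_fraction: float
    molar_coefficient: float
    components: Mapping[str, float]  # component id -> molar ratio within class


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular composition feeding the biomass objective function.

    Keys are class names (carbohydrate, protein, lipid, DNA, RNA,
    antenna chromophore, ...); mass fractions must sum to 1 within 0.01.
    """

    classes: Mapping[str, MacromoleculeClass]
    biomass_metabolite_id: str = "biomass"

    def validate(self) -> None:
        if not self.classes:
            raise ValueError("biomass composition has no macromolecule classes")
        total = sum(c.mass_fraction for c in self.classes.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"mass fractions sum to {total:.4f}, expected 1 +/- 0.01")
        for name, cls in self.classes.items():
            if cls.molar_coefficient <= 0:
                raise ValueError(f"class {name!r} has non-positive molar coefficient")
            if not cls.components:
                raise ValueError(f"class {name!r} lists no components")
            for comp, ratio in cls.components.items():
                if ratio <= 0:
                    raise ValueError(f"component {comp!r} of {name!r} has non-positive ratio")


@dataclass(frozen=True)
class ModelStatistics:
    n_genes: int
    n_reactions: int
    n_internal: int
    n_exchange: int
    n_gene_associated: int
    n_orphan: int
    n_metabolites: int
    n_reversible_internal: int
    n_irreversible_internal: int


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(model: MetabolicModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Assemble S (balanced metabolites x reactions).

    Returns ``(S, row_ids, col_ids)``.  Boundary metabolites are excluded
    from the rows: they only open the system and carry no balance.
    """
    rows = model.balanced_metabolites()
    row_index = {m.id: i for i, m in enumerate(rows)}
    known = {m.id for m in model.metabolites}
    S = np.zeros((len(rows), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in known:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            i = row_index.get(met_id)
            if i is not None:
                S[i, j] = coeff
    return S, [m.id for m in rows], [r.id for r in model.reactions]


def metabolite_connectivity(model: MetabolicModel) -> dict[str, int]:
    """Number of distinct reactions each metabolite participates in.

    Participation means a non-zero stoichiometric coefficient; a metabolite
    appearing twice in one reaction still counts that reaction once.
    """
    counts = {m.id: 0 for m in model.metabolites}
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff != 0 and met_id in counts:
                counts[met_id] += 1
    return counts


def top_connected_metabolites(model: MetabolicModel, k: int = 10) -> list[tuple[str, int]]:
    """The k network hubs, sorted by descending connectivity then id."""
    conn = metabolite_connectivity(model)
    return sorted(conn.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def find_dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that are only ever produced or only ever consumed.

    A reversible reaction counts as both a producer and a consumer of every
    participant.  Metabolites touched by an exchange reaction are excluded
    (the boundary can absorb or supply them), as are boundary metabolites.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    exchange_connected: set[str] = set()
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            if rxn.is_exchange:
                exchange_connected.add(met_id)
                continue
            if rxn.reversible:
                produced.add(met_id)
                consumed.add(met_id)
            elif coeff > 0:
                produced.add(met_id)
            else:
                consumed.add(met_id)
    dead: set[str] = set()
    for met in model.metabolites:
        if met.compartment is Compartment.BOUNDARY or met.id in exchange_connected:
            continue
        is_produced = met.id in produced
        is_consumed = met.id in consumed
        if is_produced != is_consumed:  # one-sided participation
            dead.add(met.id)
    return dead


def assemble_biomass_reaction(
    composition: BiomassComposition,
    reaction_id: str = "biomass",
    name: str = "biomass objective function",
) -> Reaction:
    """Build the biomass pseudo-reaction from a composition table.

    Each component is drained with coefficient
    ``class_molar_coefficient * component_ratio``; one unit of the biomass
    metabolite is produced.  The reaction is irreversible and has no gene
    association.
    """
    composition.validate()
    stoich: dict[str, float] = {}
    for cls in composition.classes.values():
        for comp_id, ratio in cls.components.items():
            stoich[comp_id] = stoich.get(comp_id, 0.0) - cls.molar_coefficient * ratio
    stoich[composition.biomass_metabolite_id] = 1.0
    return Reaction(
        id=reaction_id,
        name=name,
        stoichiometry=stoich,
        reversible=False,
        lower_bound=0.0,
        upper_bound=INF,
        subsystem="Biomass",
    )


def model_statistics(model: MetabolicModel) -> ModelStatistics:
    internal = model.internal_reactions
    exchange = model.exchange_reactions
    gene_associated = [r for r in internal if not r.gpr.is_empty]
    reversible = [r for r in internal if r.reversible]
    return ModelStatistics(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_internal=len(internal),
        n_exchange=len(exchange),
        n_gene_associated=len(gene_associated),
        n_orphan=len(internal) - len(gene_associated),
        n_metabolites=len(model.metabolites),
        n_reversible_internal=len(reversible),
        n_irreversible_internal=len(internal) - len(reversible),
    )


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthy when clean, mirroring "report empty <=> valid"
        return self.ok


def validate_model(model: MetabolicModel, declared_genes: Iterable[str] | None = None) -> ValidationReport:
    """Structural validation. Never raises; returns a report of issues."""
    report = ValidationReport()
    seen_mets: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_mets:
            report.issues.append(f"duplicate metabolite id {m.id!r}")
        seen_mets.add(m.id)
    seen_rxns: set[str] = set()
    for r in model.reactions:
        if r.id in seen_rxns:
            report.issues.append(f"duplicate reaction id {r.id!r}")
        seen_rxns.add(r.id)
        for met_id in r.stoichiometry:
            if met_id not in seen_mets and met_id not in {m.id for m in model.metabolites}:
                report.issues.append(
                    f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                )
        if r.lower_bound > r.upper_bound:
            report.issues.append(
                f"reaction {r.id!r} has lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if not r.reversible and r.lower_bound < 0:
            report.issues.append(
                f"irreversible reaction {r.id!r} has negative lower_bound {r.lower_bound}"
            )
        if not r.stoichiometry and not r.is_exchange:
            report.issues.append(f"reaction {r.id!r} has empty stoichiometry")
    if declared_genes is not None:
        declared = set(declared_genes)
        for r in model.reactions:
            for g in r.gpr.genes():
                if g not in declared:
                    report.issues.append(
                        f"reaction {r.id!r} GPR references undeclared gene {g!r}"
                    )
    if not model.objective_reaction_id:
        report.issues.append("model has no objective reaction")
    elif not model.has_reaction(model.objective_reaction_id):
        report.issues.append(
            f"objective reaction {model.objective_reaction_id!r} not in model"
        )
    return report


def check_elemental_balance(model: MetabolicModel, rxn: Reaction) -> dict[str, float] | None:
    """Net element counts of a reaction, or None if any formula is missing.

    Advisory only: a mass-balanced reaction nets to zero for every element.
    Exchange reactions are inherently unbalanced and return None.
    """
    if rxn.is_exchange:
        return None
    net: dict[str, float] = {}
    for met_id, coeff in rxn.stoichiometry.items():
        formula = model.metabolite(met_id).formula
        if formula is None:
            return None
        for element, count in formula.items():
            net[element] = net.get(element, 0.0) + coeff * count
    return net
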