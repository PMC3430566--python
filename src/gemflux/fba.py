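"""Flux balance analysis.

Solves the steady-state LP

    max  c'v
    s.t. S v = 0,   lb <= v <= ub

with HiGHS through :func:`scipy.optimize.linprog`.  The dual simplex method
is pinned and variables follow the model's reaction order, so repeated
solves of the same problem return the same vertex.  Note that only the
optimal *objective value* is unique: the flux vector of a degenerate LP
depends on the solver's tie-breaking, which is why derived quantities such
as active-reaction counts are solver-path dependent.

Shadow prices (the duals of the metabolite balance rows) are reported with
the convention γ_i = ∂z/∂(availability of metabolite i): a positive price
marks a growth-limiting metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.optimize import linprog

from .core import MetabolicModel, Reaction, build_stoichiometric_matrix, INF
from .io.conditions import ConditionConfig

#: fluxes with magnitude at or below this are treated as zero
ZERO_EPSILON = 1e-9

#: relative tolerance on the steady-state residual of reported optima
FEASIBILITY_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass(frozen=True)
class ObjectiveSpec:
    """Linear objective c over reactions; default is the biomass reaction."""

    coefficients: dict[str, float]
    sense: str = "max"

    def __post_init__(self):
        if not any(self.coefficients.values()):
            raise ValueError("objective must have at least one non-zero coefficient")
        if self.sense not in ("max", "min"):
            raise ValueError(f"objective sense must be 'max' or 'min', not {self.sense!r}")

    @staticmethod
    def biomass(model: MetabolicModel) -> "ObjectiveSpec":
        if not model.objective_reaction_id:
            raise ValueError("model has no objective reaction")
        return ObjectiveSpec({model.objective_reaction_id: 1.0})


@dataclass
class FluxSolution:
    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    shadow_prices: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class ConditionError(KeyError):
    """A condition references an exchange reaction absent from the model."""


def resolve_exchange(model: MetabolicModel, key: str) -> str:
    """Map a condition key (metabolite name or reaction id) to an exchange id."""
    for candidate in (key, f"EX_{key}"):
        if model.has_reaction(candidate) and model.reaction(candidate).is_exchange:
            return candidate
    available = ", ".join(r.id for r in model.exchange_reactions)
    raise ConditionError(
        f"condition key {key!r} matches no exchange reaction; model exchanges: {available}"
    )


def apply_condition(model: MetabolicModel, condition: ConditionConfig) -> MetabolicModel:
    """Constrain exchange bounds to a growth condition.

    Exchanges are written in the export direction, so an uptake pair
    ``(lo, hi)`` becomes flux bounds ``(-hi, -lo)``.  Exchanges named in
    ``condition.free`` are opened in both directions; every other exchange
    is closed for uptake with secretion left open.
    """
    explicit = {resolve_exchange(model, key): pair for key, pair in condition.uptakes.items()}
    free = {
        resolve_exchange(model, key)
        for key in condition.free
        if any(
            model.has_reaction(c) and model.reaction(c).is_exchange
            for c in (key, f"EX_{key}")
        )
    }
    new_reactions: list[Reaction] = []
    for rxn in model.reactions:
        if not rxn.is_exchange:
            new_reactions.append(rxn)
        elif rxn.id in explicit:
            lo, hi = explicit[rxn.id]
            new_reactions.append(rxn.with_bounds(-hi, -lo))
        elif rxn.id in free:
            new_reactions.append(rxn.with_bounds(-INF, INF))
        else:
            new_reactions.append(rxn.with_bounds(0.0, INF))
    return model.with_reactions(new_reactions)


def solve_fba(model: MetabolicModel, objective: ObjectiveSpec | None = None) -> FluxSolution:
    """Solve the FBA linear program; never raises on solver failure."""
    if objective is None:
        objective = ObjectiveSpec.biomass(model)
    S, row_ids, col_ids = build_stoichiometric_matrix(model)
    sign = -1.0 if objective.sense == "max" else 1.0
    c = np.zeros(len(col_ids))
    for rxn_id, coeff in objective.coefficients.items():
        if rxn_id not in model._rxn_index:
            raise KeyError(f"objective references unknown reaction {rxn_id!r}")
        c[model._rxn_index[rxn_id]] = sign * coeff
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c,
        A_eq=scipy.sparse.csr_matrix(S) if S.size else None,
        b_eq=np.zeros(len(row_ids)) if S.size else None,
        bounds=bounds,
        method="highs-ds",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), message=res.message)
    fluxes = dict(zip(col_ids, (float(x) for x in res.x)))
    duals = res.eqlin.marginals if res.eqlin is not None else np.zeros(len(row_ids))
    # linprog minimizes and its row marginals are d(min)/db.  Availability u of
    # metabolite i enters the balance as S v = -u e_i, so in the max sense
    # gamma_i = dz/du = -sign * marginal_i (positive = growth-limiting).
    shadow = dict(zip(row_ids, (float(-sign * m) for m in duals)))
    objective_value = float(res.fun) if objective.sense == "min" else float(-res.fun)
    return FluxSolution(
        status=status,
        objective_value=objective_value + 0.0,  # normalize IEEE negative zero
        fluxes=fluxes,
        shadow_prices=shadow,
    )


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """‖S·v‖∞ of a solution; optimal solutions keep this at solver tolerance."""
    S, _, col_ids = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[r] for r in col_ids])
    return float(np.abs(S @ v).max()) if S.size else 0.0


def simulate_growth_conditions(
    model: MetabolicModel, conditions: list[ConditionConfig]
) -> pd.DataFrame:
    """One FBA per condition.  Infeasible conditions report growth 0 (the
    status column preserves the solver verdict)."""
    rows = []
    for condition in conditions:
        constrained = apply_condition(model, condition)
        sol = solve_fba(constrained)
        rows.append(
            {
                "condition": condition.name,
                "status": sol.status,
                "growth_rate": sol.objective_value if sol.ok else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["condition", "status", "growth_rate"])


def genes_to_disabled_reactions(model: MetabolicModel, knocked_genes: set[str]) -> set[str]:
    """Reactions whose GPR evaluates false with the knocked genes absent."""
    unknown = set(knocked_genes) - model.genes
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    knocked = frozenset(knocked_genes)
    return {
        rxn.id
        for rxn in model.reactions
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(knocked)
    }


def knockout_model(model: MetabolicModel, knocked_genes: set[str]) -> MetabolicModel:
    """The mutant model: disabled reactions get zero bounds."""
    disabled = genes_to_disabled_reactions(model, knocked_genes)
    return model.with_reactions(
        [r.with_bounds(0.0, 0.0) if r.id in disabled else r for r in model.reactions]
    )


def single_gene_deletion_fba(
    model: MetabolicModel, gene: str, condition: ConditionConfig | None = None
) -> FluxSolution:
    """FBA optimum of the single-gene mutant (condition applied first if given)."""
    constrained = apply_condition(model, condition) if condition is not None else model
    return solve_fba(knockout_model(constrained, {gene}))


def active_reactions(solution: FluxSolution, epsilon: float = ZERO_EPSILON) -> set[str]:
    """Reactions carrying non-zero flux (|v| > epsilon) in a solution."""
    if not solution.ok:
        raise ValueError(f"cannot extract active reactions from a {solution.status} solution")
    return {rxn_id for rxn_id, v in solution.fluxes.items() if abs(v) > epsilon}
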