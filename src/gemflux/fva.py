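"""Flux variability analysis and the three-way activity classification.

FVA first maximizes the biomass objective, pins it (equality with a small
relative slack), then minimizes and maximizes every reaction flux in turn.
A reaction is then

* **always active**  — min and max are non-zero with the same sign,
* **sometimes active** — the range [min, max] contains zero,
* **never active**  — min and max are both zero,

with magnitudes at or below epsilon rounded to zero first.  The classes are
exhaustive and mutually exclusive.  "Active" without qualification means
always ∪ sometimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MetabolicModel
from .fba import ObjectiveSpec, ZERO_EPSILON, apply_condition, solve_fba
from .io.conditions import ConditionConfig

#: relative slack when pinning the objective at its optimum
OPTIMUM_SLACK = 1e-6

ALWAYS = "always_active"
SOMETIMES = "sometimes_active"
NEVER = "never_active"


@dataclass
class FVAResult:
    """Per-reaction flux ranges at (a fraction of) the fixed optimal objective."""

    objective_value: float
    fraction: float
    ranges: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rxn, lo, hi) for rxn, (lo, hi) in self.ranges.items()],
            columns=["reaction", "min_flux", "max_flux"],
        )


class InfeasibleBaseProblem(RuntimeError):
    """The condition admits no optimum, so no per-reaction LP can be posed."""


def fva(
    model: MetabolicModel,
    condition: ConditionConfig | None = None,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Flux ranges of every reaction at ``fraction`` of the biomass optimum.

    The default ``fraction=1.0`` keeps the paper-style reading: ranges of
    fluxes that still satisfy the same optimal growth.  Raises
    :class:`InfeasibleBaseProblem` before any per-reaction solve if the base
    FBA fails.
    """
    constrained = apply_condition(model, condition) if condition is not None else model
    base = solve_fba(constrained)
    if not base.ok:
        raise InfeasibleBaseProblem(f"base FBA is {base.status}: {base.message}")
    z_opt = base.objective_value
    slack = abs(z_opt) * OPTIMUM_SLACK
    target_lo = fraction * z_opt - slack
    target_hi = z_opt + slack if fraction == 1.0 else None

    biomass_id = constrained.objective_reaction_id
    pinned_reactions = []
    for rxn in constrained.reactions:
        if rxn.id == biomass_id:
            upper = min(rxn.upper_bound, target_hi) if target_hi is not None else rxn.upper_bound
            pinned_reactions.append(rxn.with_bounds(max(rxn.lower_bound, target_lo), upper))
        else:
            pinned_reactions.append(rxn)
    pinned = constrained.with_reactions(pinned_reactions)

    wanted = reactions if reactions is not None else [r.id for r in pinned.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in wanted:
        lo = solve_fba(pinned, ObjectiveSpec({rxn_id: 1.0}, sense="min"))
        hi = solve_fba(pinned, ObjectiveSpec({rxn_id: 1.0}, sense="max"))
        if not (lo.ok and hi.ok):
            raise RuntimeError(
                f"FVA sub-problem for {rxn_id!r} failed ({lo.status}/{hi.status})"
            )
        vmin, vmax = lo.objective_value, hi.objective_value
        if vmin > vmax:  # solver jitter on a pinned flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rxn_id] = (vmin, vmax)
    return FVAResult(objective_value=z_opt, fraction=fraction, ranges=ranges)


def _round_eps(x: float, epsilon: float) -> float:
    return 0.0 if abs(x) <= epsilon else x


def classify_activity(result: FVAResult, epsilon: float = ZERO_EPSILON) -> dict[str, str]:
    """Map each reaction to always/sometimes/never active (see module docstring)."""
    classes: dict[str, str] = {}
    for rxn_id, (vmin, vmax) in result.ranges.items():
        lo, hi = _round_eps(vmin, epsilon), _round_eps(vmax, epsilon)
        if lo == 0.0 and hi == 0.0:
            classes[rxn_id] = NEVER
        elif lo > 0.0 or hi < 0.0:  # non-zero with the same sign
            classes[rxn_id] = ALWAYS
        else:
            classes[rxn_id] = SOMETIMES
    return classes


def class_counts(classes: dict[str, str]) -> dict[str, int]:
    counts = {ALWAYS: 0, SOMETIMES: 0, NEVER: 0}
    for cls in classes.values():
        counts[cls] += 1
    return counts


def active_set(classes: dict[str, str]) -> set[str]:
    """Reactions that can carry flux at the optimum: always ∪ sometimes."""
    return {rxn for rxn, cls in classes.items() if cls != NEVER}


def compare_condition_activity(
    classes_a: dict[str, str], classes_b: dict[str, str]
) -> tuple[set[str], set[str], set[str]]:
    """(shared active, active only in A, active only in B)."""
    if set(classes_a) != set(classes_b):
        raise ValueError("activity classifications cover different reaction universes")
    a, b = active_set(classes_a), active_set(classes_b)
    return a & b, a - b, b - a
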