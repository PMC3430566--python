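"""Exhaustive reference solvers for small networks.

These enumerate geometry instead of running an iterative solver, so they
serve as independent cross-checks of the LP/QP engines on networks with at
most ~8 reactions:

* :func:`enumerate_vertices` — all vertices of {v : S v = 0, lb ≤ v ≤ ub},
  found by fixing every choice of n − rank(S) coordinates at a bound and
  solving the remaining square system.
* :func:`bruteforce_fba` / :func:`bruteforce_fva` — optimize over the
  vertex list (LP optima and coordinate ranges are attained at vertices of
  the bounded polytope).
* :func:`bruteforce_moma` — strictly convex QP by face enumeration: for
  every assignment of coordinates to {free, at lower, at upper} solve the
  equality-constrained projection in closed form and keep the best feasible
  candidate.

Infinite bounds are replaced by ±``box_cap`` (the enumeration needs a
bounded box); callers must pick a cap safely above any attainable flux.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .core import MetabolicModel, build_stoichiometric_matrix

DEFAULT_BOX_CAP = 1e4


def _boxed_bounds(model: MetabolicModel, box_cap: float) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([max(r.lower_bound, -box_cap) for r in model.reactions])
    ub = np.array([min(r.upper_bound, box_cap) for r in model.reactions])
    return lb, ub


def enumerate_vertices(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb ≤ v ≤ ub} (rows of the result)."""
    n = S.shape[1] if S.size else len(lb)
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for fixed_idx in combinations(range(n), n_fix):
        free_idx = [i for i in range(n) if i not in fixed_idx]
        S_free = S[:, free_idx] if S.size else np.zeros((0, len(free_idx)))
        if free_idx and np.linalg.matrix_rank(S_free) < len(free_idx):
            continue  # fixed set does not determine a unique point
        for choice in product(*[(lb[i], ub[i]) for i in fixed_idx]):
            v = np.empty(n)
            for i, val in zip(fixed_idx, choice):
                v[i] = val
            if free_idx:
                rhs = -(S[:, list(fixed_idx)] @ np.array(choice)) if S.size else np.zeros(0)
                sol, residual, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                if np.abs(S_free @ sol - rhs).max() > tol * 10:
                    continue
                v[free_idx] = sol
            scale = max(1.0, float(np.abs(v).max()))
            if np.any(v < lb - tol * scale) or np.any(v > ub + tol * scale):
                continue
            if S.size and np.abs(S @ v).max() > tol * 10 * scale:
                continue
            # strict absolute dedup: nearby-but-distinct vertices (e.g. the
            # objective-slack face) must not collapse onto each other
            if not any(np.abs(v - u).max() <= 1e-9 for u in vertices):
                vertices.append(v)
    return np.array(vertices) if vertices else np.zeros((0, n))


def bruteforce_fba(
    model: MetabolicModel,
    objective_reaction: str | None = None,
    sense: str = "max",
    box_cap: float = DEFAULT_BOX_CAP,
) -> tuple[float, np.ndarray]:
    """LP optimum by vertex enumeration; returns (objective, argmax vertex)."""
    S, _, col_ids = build_stoichiometric_matrix(model)
    lb, ub = _boxed_bounds(model, box_cap)
    vertices = enumerate_vertices(S, lb, ub)
    if vertices.shape[0] == 0:
        raise RuntimeError("no feasible vertex found (infeasible or cap too small)")
    j = col_ids.index(objective_reaction or model.objective_reaction_id)
    values = vertices[:, j]
    k = int(np.argmax(values)) if sense == "max" else int(np.argmin(values))
    return float(values[k]), vertices[k]


def bruteforce_fva(
    model: MetabolicModel,
    fraction: float = 1.0,
    box_cap: float = DEFAULT_BOX_CAP,
    slack: float = 1e-6,
) -> dict[str, tuple[float, float]]:
    """FVA ranges by vertex enumeration of the optimum-pinned polytope."""
    S, _, col_ids = build_stoichiometric_matrix(model)
    lb, ub = _boxed_bounds(model, box_cap)
    z_opt, _ = bruteforce_fba(model, box_cap=box_cap)
    j = col_ids.index(model.objective_reaction_id)
    lb2, ub2 = lb.copy(), ub.copy()
    margin = abs(z_opt) * slack
    lb2[j] = max(lb2[j], fraction * z_opt - margin)
    if fraction == 1.0:
        ub2[j] = min(ub2[j], z_opt + margin)
    vertices = enumerate_vertices(S, lb2, ub2)
    if vertices.shape[0] == 0:
        raise RuntimeError("optimum-pinned polytope has no vertices")
    return {
        rxn_id: (float(vertices[:, k].min()), float(vertices[:, k].max()))
        for k, rxn_id in enumerate(col_ids)
    }


def bruteforce_moma(
    S: np.ndarray,
    w: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-8,
) -> np.ndarray | None:
    """Exact strictly convex QP by exhaustive face enumeration.

    For each of the 3^n assignments of coordinates to {free, lower, upper}
    the equality-constrained projection of w is solved via its KKT system;
    the feasible candidate with the smallest distance is the global optimum
    (the optimum lies in the relative interior of some face, where it is
    the affine projection).  Returns None if no face yields a feasible
    point (infeasible problem).
    """
    n = len(w)
    best: np.ndarray | None = None
    best_val = np.inf
    for assignment in product((0, 1, 2), repeat=n):
        fixed_vals = {}
        free_idx = []
        for i, a in enumerate(assignment):
            if a == 0:
                free_idx.append(i)
            elif a == 1:
                if not np.isfinite(lb[i]):
                    break
                fixed_vals[i] = lb[i]
            else:
                if not np.isfinite(ub[i]):
                    break
                fixed_vals[i] = ub[i]
        else:
            v = np.empty(n)
            for i, val in fixed_vals.items():
                v[i] = val
            if free_idx:
                Sf = S[:, free_idx] if S.size else np.zeros((0, len(free_idx)))
                rhs = (
                    -sum(S[:, i] * val for i, val in fixed_vals.items())
                    if S.size and fixed_vals
                    else np.zeros(S.shape[0] if S.size else 0)
                )
                m = Sf.shape[0]
                K = np.block([[np.eye(len(free_idx)), Sf.T], [Sf, np.zeros((m, m))]])
                rhs_full = np.concatenate([w[free_idx], rhs])
                sol, *_ = np.linalg.lstsq(K, rhs_full, rcond=None)
                v[free_idx] = sol[: len(free_idx)]
                if m and np.abs(Sf @ v[free_idx] - rhs).max() > tol * 100:
                    continue
            scale = max(1.0, float(np.abs(v).max()))
            if np.any(v < lb - tol * scale) or np.any(v > ub + tol * scale):
                continue
            if S.size and np.abs(S @ v).max() > tol * 100 * scale:
                continue
            val = float(np.dot(v - w, v - w))
            if val < best_val - 1e-14:
                best, best_val = np.clip(v, lb, ub), val
    return best
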