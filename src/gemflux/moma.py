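"""Minimization of metabolic adjustment (MOMA) and gene essentiality.

MOMA predicts the flux state of a knockout mutant as the point of the
mutant's feasible space nearest (Euclidean distance) to a wild-type
reference flux vector:

    min  Σ_i (v_i - w_i)²
    s.t. S v = 0,  mutant bounds,  disabled reactions fixed at 0.

The mutant is not assumed to re-optimize growth; its biomass flux
(grRateKO) is whatever the projection yields.  A gene is essential when its
deletion leaves no positive biomass flux (grRateKO below a small fraction
of grRateWT).

The QP is strictly convex (identity Hessian).  It is solved with
scipy's trust-constr and then polished by solving the KKT system of the
detected active set exactly; the polish is only accepted when it is
feasible and does not worsen the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import MetabolicModel, build_stoichiometric_matrix
from .fba import (
    FluxSolution,
    apply_condition,
    genes_to_disabled_reactions,
    knockout_model,
    solve_fba,
)
from .io.conditions import ConditionConfig

#: grRateKO below this fraction of grRateWT counts as "no positive biomass flux"
ESSENTIALITY_THRESHOLD = 1e-6

#: acceptable KKT / feasibility residual of a QP solution
QP_TOL = 1e-6


@dataclass
class MomaSolution:
    status: str
    fluxes: dict[str, float] = field(default_factory=dict)
    distance: float = float("nan")
    gr_rate_ko: float = 0.0
    gr_rate_wt: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    @property
    def gr_ratio(self) -> float:
        if self.gr_rate_wt == 0.0:
            return float("nan")
        return self.gr_rate_ko / self.gr_rate_wt


def _is_feasible(S: np.ndarray, v: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> bool:
    tol = 1e-9 * max(1.0, float(np.abs(v).max()))
    if np.any(v < lb - tol) or np.any(v > ub + tol):
        return False
    return (not S.size) or float(np.abs(S @ v).max()) <= tol


def _l1_projection(S: np.ndarray, w: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray | None:
    """min Σ|v−w| s.t. Sv=0, bounds — LP warm start near the L2 optimum.

    Also serves as the feasibility probe (None when the mutant space is empty).
    """
    n = len(w)
    m = S.shape[0] if S.size else 0
    eye = np.eye(n)
    # variables [v, t] with t >= |v - w|
    A_ub = np.block([[eye, -eye], [-eye, -eye]])
    b_ub = np.concatenate([w, -w])
    A_eq = np.hstack([S, np.zeros((m, n))]) if m else None
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(m) if m else None,
        bounds=list(zip(lb, ub)) + [(0.0, None)] * n,
        method="highs",
    )
    if res.status != 0:
        return None
    return np.clip(res.x[:n], lb, ub)


def _solve_qp(S: np.ndarray, w: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray | None:
    """min ½‖v−w‖² s.t. S v = 0, lb ≤ v ≤ ub.  Returns None when infeasible.

    Primal active-set method: starting from a feasible point, repeatedly
    solve the projection restricted to the current face exactly (KKT
    system), step to the first blocking bound, and release bounds whose
    multiplier has the wrong sign.  The problem is strictly convex, so the
    method terminates at the unique optimum.
    """
    if _is_feasible(S, w, lb, ub):
        return w.copy()  # the reference is already in the mutant space
    x0 = _l1_projection(S, w, lb, ub)
    if x0 is None:
        return None
    return _active_set_qp(S, w, lb, ub, np.clip(x0, lb, ub))


def _active_set_qp(
    S: np.ndarray, w: np.ndarray, lb: np.ndarray, ub: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    n = len(w)
    x = x0.copy()
    scale = max(1.0, float(np.abs(x0).max()), float(np.abs(w).max()))
    tol = 1e-9 * scale
    equality = np.isfinite(lb) & np.isfinite(ub) & (ub - lb <= tol)  # never released
    at_lo = np.isfinite(lb) & (x - lb <= tol)
    at_hi = np.isfinite(ub) & (ub - x <= tol)
    for _ in range(20 * n + 50):
        fixed = at_lo | at_hi
        b_fixed = np.where(at_hi, ub, lb)
        cand, lam = _solve_face(S, w, fixed, b_fixed)
        if cand is None:  # inconsistent face: release the most recent bound
            break
        d = cand - x
        if float(np.abs(d).max()) <= tol:
            # at the face optimum: check bound-multiplier signs
            stationarity = (x - w) + (S.T @ lam if S.size else 0.0)
            release_lo = at_lo & ~equality & (stationarity < -tol)
            release_hi = at_hi & ~equality & (stationarity > tol)
            violation = np.where(release_lo, -stationarity, 0.0) + np.where(
                release_hi, stationarity, 0.0
            )
            if violation.max() <= tol:
                return np.clip(x, lb, ub)  # KKT satisfied: unique optimum
            worst = int(np.argmax(violation))
            if release_lo[worst]:
                at_lo[worst] = False
            else:
                at_hi[worst] = False
            continue
        # longest feasible step toward the face optimum
        alpha = 1.0
        blocking: tuple[int, str] | None = None
        for i in np.nonzero(~fixed)[0]:
            if d[i] > tol and np.isfinite(ub[i]):
                a = (ub[i] - x[i]) / d[i]
                if a < alpha:
                    alpha, blocking = a, (i, "hi")
            elif d[i] < -tol and np.isfinite(lb[i]):
                a = (lb[i] - x[i]) / d[i]
                if a < alpha:
                    alpha, blocking = a, (i, "lo")
        x = np.clip(x + alpha * d, lb, ub)
        if blocking is not None and alpha < 1.0:
            i, side = blocking
            (at_hi if side == "hi" else at_lo)[i] = True
        else:
            x = np.clip(cand, lb, ub)
    return np.clip(x, lb, ub)


def kkt_residual(
    S: np.ndarray, w: np.ndarray, lb: np.ndarray, ub: np.ndarray, v: np.ndarray
) -> float:
    """Best-achievable stationarity residual of a candidate optimum.

    A feasible ``v`` is the (unique) optimum iff multipliers exist with
    ``(v−w) + Sᵀλ − μ_lo + μ_hi = 0``, ``μ ≥ 0`` and μ supported only on
    the active bounds.  The residual is ‖·‖∞ of that equation minimized
    over admissible multipliers (sign-constrained least squares); it is 0
    exactly at the solution.
    """
    from scipy.optimize import nnls

    scale = max(1.0, float(np.abs(v).max()))
    tol = 1e-7 * scale
    at_lo = np.where(np.isfinite(lb) & (v - lb <= tol))[0]
    at_hi = np.where(np.isfinite(ub) & (ub - v <= tol))[0]
    n = len(v)
    m = S.shape[0] if S.size else 0
    # all variables non-negative: free lambda split into positive/negative parts
    blocks = []
    if m:
        blocks += [S.T, -S.T]
    if at_lo.size:
        E = np.zeros((n, at_lo.size))
        E[at_lo, np.arange(at_lo.size)] = -1.0
        blocks.append(E)
    if at_hi.size:
        E = np.zeros((n, at_hi.size))
        E[at_hi, np.arange(at_hi.size)] = 1.0
        blocks.append(E)
    b = -(v - w)
    if not blocks:
        return float(np.abs(b).max())
    A = np.hstack(blocks)
    x, _ = nnls(A, b)
    return float(np.abs(A @ x - b).max())


def _solve_face(
    S: np.ndarray,
    w: np.ndarray,
    fixed: np.ndarray,
    b_fixed: np.ndarray,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Exact minimizer of ½‖v−w‖² s.t. Sv=0 with coordinates ``fixed`` pinned.

    Returns ``(point, balance_multipliers)``; the point is None when the
    face is inconsistent with the balance constraints.
    """
    n = len(w)
    m = S.shape[0] if S.size else 0
    free = ~fixed
    nf = int(free.sum())
    if nf == 0:
        cand = b_fixed.copy()
        lam = np.zeros(m)
        if m and np.abs(S @ cand).max() > 1e-7 * max(1.0, float(np.abs(cand).max())):
            return None, lam
        return cand, lam
    Sf = S[:, free] if S.size else np.zeros((0, nf))
    rhs_eq = (
        -(S[:, fixed] @ b_fixed[fixed]) if S.size and fixed.any() else np.zeros(m)
    )
    K = np.block([[np.eye(nf), Sf.T], [Sf, np.zeros((m, m))]])
    rhs = np.concatenate([w[free], rhs_eq])
    try:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return None, np.zeros(m)
    cand = np.empty(n)
    cand[fixed] = b_fixed[fixed]
    cand[free] = sol[:nf]
    lam = sol[nf:]
    if m and np.abs(Sf @ cand[free] - rhs_eq).max() > 1e-7 * max(1.0, float(np.abs(cand).max())):
        return None, lam  # face is inconsistent with the balance
    return cand, lam


def moma(
    model: MetabolicModel,
    wild_type_flux: FluxSolution,
    knocked_genes: set[str],
) -> MomaSolution:
    """MOMA projection of the wild-type flux onto the mutant's feasible space.

    ``model`` must already carry the growth condition under which
    ``wild_type_flux`` was obtained.
    """
    if not wild_type_flux.ok:
        raise ValueError("wild-type reference solution is not optimal")
    mutant = knockout_model(model, knocked_genes) if knocked_genes else model
    S, _, col_ids = build_stoichiometric_matrix(mutant)
    w = np.array([wild_type_flux.fluxes[r] for r in col_ids])
    lb = np.array([r.lower_bound for r in mutant.reactions])
    ub = np.array([r.upper_bound for r in mutant.reactions])
    gr_wt = wild_type_flux.objective_value

    v = _solve_qp(S, w, lb, ub)
    if v is None:
        return MomaSolution(status="infeasible", gr_rate_ko=0.0, gr_rate_wt=gr_wt)
    fluxes = dict(zip(col_ids, (float(x) for x in v)))
    return MomaSolution(
        status="optimal",
        fluxes=fluxes,
        distance=float(np.linalg.norm(v - w)),
        gr_rate_ko=fluxes[model.objective_reaction_id],
        gr_rate_wt=gr_wt,
    )


def single_gene_deletion_moma(
    model: MetabolicModel, gene: str, condition: ConditionConfig | None = None
) -> MomaSolution:
    constrained = apply_condition(model, condition) if condition is not None else model
    wild_type = solve_fba(constrained)
    if not wild_type.ok:
        raise ValueError(f"wild type is {wild_type.status} under this condition")
    return moma(constrained, wild_type, {gene})


@dataclass
class EssentialityReport:
    condition: str
    method: str
    gr_rate_wt: float
    wild_type_fluxes: dict[str, float]
    table: pd.DataFrame  # columns: gene, grRateKO, grRateWT, grRatio, essential, status

    @property
    def essential_genes(self) -> set[str]:
        return set(self.table.loc[self.table["essential"], "gene"])


def essentiality_screen(
    model: MetabolicModel,
    condition: ConditionConfig | None = None,
    method: str = "moma",
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> EssentialityReport:
    """Single-gene deletion screen over every gene of the model.

    ``method`` is ``"moma"`` (quadratic projection from the wild-type
    optimum) or ``"fba"`` (mutant re-optimizes growth).  Genes whose
    deletion disables no reaction keep the wild-type growth without a
    solve.  Per-gene solver failures are recorded and the screen continues.
    """
    if method not in ("moma", "fba"):
        raise ValueError(f"method must be 'moma' or 'fba', not {method!r}")
    constrained = apply_condition(model, condition) if condition is not None else model
    wild_type = solve_fba(constrained)
    if not wild_type.ok:
        raise ValueError(f"wild type is {wild_type.status} under this condition")
    gr_wt = wild_type.objective_value

    rows = []
    for gene in sorted(constrained.genes):
        disabled = genes_to_disabled_reactions(constrained, {gene})
        if not disabled:
            gr_ko, status = gr_wt, "optimal"
        elif all(abs(wild_type.fluxes[r]) == 0.0 for r in disabled) and method == "moma":
            # wild-type vector already feasible for the mutant: distance 0
            gr_ko, status = gr_wt, "optimal"
        elif method == "moma":
            sol = moma(constrained, wild_type, {gene})
            gr_ko, status = (sol.gr_rate_ko, sol.status) if sol.ok else (0.0, sol.status)
        else:
            sol = solve_fba(knockout_model(constrained, {gene}))
            gr_ko, status = (sol.objective_value, sol.status) if sol.ok else (0.0, sol.status)
        essential = gr_ko < threshold * gr_wt if gr_wt > 0 else True
        rows.append(
            {
                "gene": gene,
                "grRateKO": gr_ko,
                "grRateWT": gr_wt,
                "grRatio": gr_ko / gr_wt if gr_wt > 0 else float("nan"),
                "essential": essential,
                "status": status,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "grRateKO", "grRateWT", "grRatio", "essential", "status"]
    ).sort_values(["grRatio", "gene"], na_position="first").reset_index(drop=True)
    return EssentialityReport(
        condition=condition.name if condition is not None else "(as given)",
        method=method,
        gr_rate_wt=gr_wt,
        wild_type_fluxes=dict(wild_type.fluxes),
        table=table,
    )


def compare_essential_sets(
    report_a: EssentialityReport, report_b: EssentialityReport
) -> tuple[set[str], set[str], set[str]]:
    """(common essential, essential only in A, essential only in B)."""
    genes_a = set(report_a.table["gene"])
    genes_b = set(report_b.table["gene"])
    if genes_a != genes_b:
        raise ValueError("essentiality reports cover different gene universes")
    a, b = report_a.essential_genes, report_b.essential_genes
    return a & b, a - b, b - a
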