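"""Phenotypic phase plane (PhPP) analysis.

A PhPP scans two exchange uptakes over a grid, maximizes biomass at every
point, and reads the shadow prices of the two scanned metabolites from the
LP dual.  Regions where the shadow-price pair is constant are distinct
metabolic phenotypes: a positive price on a scanned metabolite marks it as
growth-limiting there, a zero-growth band is its own region.

By default the scanned uptakes are *fixed as equalities* at each grid
point (the whole fixed supply must be consumed or re-routed; phototroph
fixtures therefore carry an explicit photon-dissipation sink).  Passing
``mode="upper"`` instead treats each grid value as an uptake cap, in which
case growth is non-decreasing along both axes by LP monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import MetabolicModel
from .fba import apply_condition, resolve_exchange, solve_fba
from .io.conditions import ConditionConfig

#: shadow prices closer than this are considered equal when segmenting
REGION_TOL = 1e-6


@dataclass(frozen=True)
class AxisSpec:
    """One scanned exchange: reaction (or condition key), range, step count."""

    exchange: str
    start: float
    stop: float
    steps: int = 50

    def __post_init__(self):
        if self.steps < 2:
            raise ValueError("an axis needs at least 2 grid points")
        if self.stop < self.start:
            raise ValueError(f"axis range [{self.start}, {self.stop}] is reversed")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.steps)

    @staticmethod
    def parse(text: str) -> "AxisSpec":
        """Parse ``"EX_photon:0:100"`` or ``"EX_photon:0:100:50"``."""
        parts = text.split(":")
        if len(parts) not in (3, 4):
            raise ValueError(f"axis spec must be 'exchange:start:stop[:steps]', got {text!r}")
        steps = int(parts[3]) if len(parts) == 4 else 50
        return AxisSpec(parts[0], float(parts[1]), float(parts[2]), steps)


@dataclass
class PhPPGrid:
    axis_x: AxisSpec
    axis_y: AxisSpec
    metabolite_x: str
    metabolite_y: str
    growth: np.ndarray        # (ny, nx)
    status: np.ndarray        # (ny, nx) of str
    gamma_x: np.ndarray       # shadow price of the x metabolite
    gamma_y: np.ndarray
    regions: np.ndarray | None = None
    boundary: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        xs, ys = self.axis_x.values, self.axis_y.values
        rows = []
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                rows.append(
                    {
                        "x": x,
                        "y": y,
                        "growth": self.growth[iy, ix],
                        "status": self.status[iy, ix],
                        "gamma_x": self.gamma_x[iy, ix],
                        "gamma_y": self.gamma_y[iy, ix],
                        "region": int(self.regions[iy, ix]) if self.regions is not None else -1,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PhaseRegion:
    region_id: int
    n_points: int
    shadow_price_pair: tuple[float, float]
    label: str
    mean_growth: float
    members: list[tuple[int, int]] = field(default_factory=list)  # (iy, ix)


def _metabolite_of_exchange(model: MetabolicModel, rxn_id: str) -> str:
    rxn = model.reaction(rxn_id)
    internal = [m for m in rxn.stoichiometry if model.metabolite(m).compartment.value != "boundary"]
    if len(internal) != 1:
        raise ValueError(f"exchange {rxn_id!r} does not have a single balanced species")
    return internal[0]


def phenotype_phase_plane(
    model: MetabolicModel,
    condition: ConditionConfig,
    axis_x: AxisSpec,
    axis_y: AxisSpec,
    mode: str = "equality",
) -> PhPPGrid:
    """Maximal growth and scanned-metabolite shadow prices over a 2-D grid."""
    if mode not in ("equality", "upper"):
        raise ValueError(f"mode must be 'equality' or 'upper', not {mode!r}")
    base = apply_condition(model, condition)
    rx = resolve_exchange(base, axis_x.exchange)
    ry = resolve_exchange(base, axis_y.exchange)
    met_x = _metabolite_of_exchange(base, rx)
    met_y = _metabolite_of_exchange(base, ry)

    nx, ny = axis_x.steps, axis_y.steps
    growth = np.zeros((ny, nx))
    gamma_x = np.zeros((ny, nx))
    gamma_y = np.zeros((ny, nx))
    status = np.empty((ny, nx), dtype=object)
    ix_x = base._rxn_index[rx]
    ix_y = base._rxn_index[ry]

    reactions = list(base.reactions)
    for iy, uy in enumerate(axis_y.values):
        for ix, ux in enumerate(axis_x.values):
            # uptake u corresponds to exchange flux -u (export convention)
            if mode == "equality":
                reactions[ix_x] = base.reactions[ix_x].with_bounds(-ux, -ux)
                reactions[ix_y] = base.reactions[ix_y].with_bounds(-uy, -uy)
            else:
                reactions[ix_x] = base.reactions[ix_x].with_bounds(-ux, 0.0)
                reactions[ix_y] = base.reactions[ix_y].with_bounds(-uy, 0.0)
            sol = solve_fba(base.with_reactions(reactions))
            status[iy, ix] = sol.status
            if sol.ok:
                growth[iy, ix] = sol.objective_value
                gamma_x[iy, ix] = sol.shadow_prices.get(met_x, 0.0)
                gamma_y[iy, ix] = sol.shadow_prices.get(met_y, 0.0)
            else:
                growth[iy, ix] = 0.0
                gamma_x[iy, ix] = np.nan
                gamma_y[iy, ix] = np.nan
    return PhPPGrid(
        axis_x=axis_x,
        axis_y=axis_y,
        metabolite_x=met_x,
        metabolite_y=met_y,
        growth=growth,
        status=status,
        gamma_x=gamma_x,
        gamma_y=gamma_y,
    )


def segment_phases(grid: PhPPGrid, tol: float = REGION_TOL) -> list[PhaseRegion]:
    """Partition the grid into connected regions of constant shadow prices.

    Zero-growth (or infeasible) points form their own region.  Points whose
    price pair sits between two regions (degenerate vertex duals) are
    assigned to the region of their lexicographically smaller neighbor and
    flagged in ``grid.boundary``.
    """
    ny, nx = grid.growth.shape
    zero_growth = (grid.growth <= tol) | (grid.status != "optimal")

    # quantize price pairs so equal-within-tol pairs share a code
    def code(iy: int, ix: int) -> tuple:
        if zero_growth[iy, ix]:
            return ("zero",)
        return (round(grid.gamma_x[iy, ix] / tol), round(grid.gamma_y[iy, ix] / tol))

    codes = {}
    coded = np.zeros((ny, nx), dtype=int)
    for iy in range(ny):
        for ix in range(nx):
            c = code(iy, ix)
            if c not in codes:
                codes[c] = len(codes) + 1
            coded[iy, ix] = codes[c]

    boundary = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            if zero_growth[iy, ix]:
                continue
            for jy, jx in ((iy - 1, ix), (iy, ix - 1)):
                if 0 <= jy < ny and 0 <= jx < nx and not zero_growth[jy, jx]:
                    gx = abs(grid.gamma_x[iy, ix] - grid.gamma_x[jy, jx])
                    gy = abs(grid.gamma_y[iy, ix] - grid.gamma_y[jy, jx])
                    if (gx > tol or gy > tol) and (gx <= 10 * tol and gy <= 10 * tol):
                        # near-tie: snap to the lexicographically smaller neighbor
                        coded[iy, ix] = coded[jy, jx]
                        boundary[iy, ix] = True

    regions = np.zeros((ny, nx), dtype=int)
    out: list[PhaseRegion] = []
    next_id = 0
    for value in np.unique(coded):
        mask = coded == value
        labeled, n_components = ndimage.label(mask)
        for comp in range(1, n_components + 1):
            comp_mask = labeled == comp
            next_id += 1
            regions[comp_mask] = next_id
            members = [(int(iy), int(ix)) for iy, ix in zip(*np.nonzero(comp_mask))]
            iy0, ix0 = members[0]
            if zero_growth[iy0, ix0]:
                label, pair = "no-growth", (0.0, 0.0)
            else:
                pair = (float(grid.gamma_x[iy0, ix0]), float(grid.gamma_y[iy0, ix0]))
                limiting = []
                if pair[0] > tol:
                    limiting.append(f"{grid.metabolite_x}-limited")
                if pair[1] > tol:
                    limiting.append(f"{grid.metabolite_y}-limited")
                label = " & ".join(limiting) if limiting else "unlimited"
            out.append(
                PhaseRegion(
                    region_id=next_id,
                    n_points=int(comp_mask.sum()),
                    shadow_price_pair=pair,
                    label=label,
                    mean_growth=float(grid.growth[comp_mask].mean()),
                    members=members,
                )
            )
    grid.regions = regions
    grid.boundary = boundary
    return out


def robustness_scan(
    model: MetabolicModel,
    condition: ConditionConfig,
    axis: AxisSpec,
    mode: str = "equality",
) -> pd.DataFrame:
    """1-D growth curve over one scanned exchange (special case of the grid)."""
    base = apply_condition(model, condition)
    rx = resolve_exchange(base, axis.exchange)
    met = _metabolite_of_exchange(base, rx)
    ix_r = base._rxn_index[rx]
    reactions = list(base.reactions)
    rows = []
    for u in axis.values:
        if mode == "equality":
            reactions[ix_r] = base.reactions[ix_r].with_bounds(-u, -u)
        else:
            reactions[ix_r] = base.reactions[ix_r].with_bounds(-u, 0.0)
        sol = solve_fba(base.with_reactions(reactions))
        rows.append(
            {
                "uptake": u,
                "growth": sol.objective_value if sol.ok else 0.0,
                "status": sol.status,
                "gamma": sol.shadow_prices.get(met, np.nan) if sol.ok else np.nan,
            }
        )
    return pd.DataFrame(rows)
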