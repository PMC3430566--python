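# Methods

## The constraint-based model

A model is a list of metabolites (rows of the stoichiometric matrix S),
reactions (columns, with signed coefficients: negative = consumed), boolean
gene–protein–reaction (GPR) rules, and one biomass objective reaction.
Fluxes are in mmol/mmol dry cell/h; the biomass flux is the specific growth
rate (1/h).  Metabolites in the `boundary` compartment exist only to open
the system (the partners of exchange reactions) and are excluded from the
steady-state balance, i.e. from the rows of S.  Irreversible reactions have
non-negative lower bounds; unbounded fluxes are internal ±∞ and serialize
as ±999999, the convention of legacy COBRA SBML files.

Growth media are expressed as positive uptake-bound pairs per exchange
metabolite.  Exchanges are written in the export direction, so a pair
(lo, hi) becomes flux bounds (−hi, −lo): a fixed pair *forces* uptake, an
explicit (0, 0) closes the exchange, unlisted exchanges default to zero
uptake with secretion open, and a configurable free list (water, protons,
common ions) is open in both directions.  The three built-in presets encode
the study media: bicarbonate 0.20 fixed (autotrophic/mixotrophic) or 0,
phosphate 0–0.0056, nitrate 0–0.040, sulfate 0–0.0014, glucose 0.017 fixed
(heterotrophic/mixotrophic) or 0, photons 0–100 (μEinstein/m²/s, treated
numerically as a flux bound; no unit conversion is attempted).

## Solvers and numerical choices

* **FBA** is solved with HiGHS dual simplex (`scipy.optimize.linprog`,
  method `highs-ds`) with variables in model reaction order.  Only the
  optimal objective value is contract-guaranteed: degenerate LPs have many
  optimal flux vectors, and the pinned method/ordering merely makes the
  returned vertex reproducible, not canonical.  Derived quantities such as
  active-reaction counts therefore depend on solver tie-breaking; published
  counts from other solvers are expected to reproduce only approximately.
* **Zero threshold**: |v| ≤ 1e−9 counts as zero flux (fluxes of interest
  are 1e−3–1e2).  Reported optima satisfy ‖S·v‖∞ ≤ 1e−9·max(1, ‖v‖∞),
  asserted in the test suite on every solve.
* **FVA** pins the biomass at 100 % of its optimum via an equality with
  relative slack 1e−6 (a fraction-of-optimum knob exists, default 1.0),
  then solves two LPs per reaction sequentially.  Classification rounds
  range endpoints with the zero threshold first, so (1e−12, 0.4) is
  *sometimes active*.
* **Shadow prices** follow γᵢ = ∂z/∂(availability of metabolite i), read
  from the HiGHS row duals with the sign fixed so that a growth-limiting
  metabolite has γ > 0; a finite-difference test pins the convention.
* **MOMA** is a strictly convex QP (identity Hessian).  It is solved by a
  primal active-set method written here: an L1-projection LP provides a
  feasible start (and the infeasibility verdict), each face projection is
  solved exactly through its KKT system, and bounds are released by
  multiplier sign.  Equality-fixed coordinates (lb = ub) are never
  released.  Optimality is certified by a non-negative-least-squares KKT
  residual ≤ 1e−6, and on small networks the solution matches an
  exhaustive face-enumeration oracle to better than 1e−12.
* **Essentiality threshold**: a gene is essential when the mutant's biomass
  flux is below 1e−6 × the wild-type optimum ("no positive flux").
  Mutants whose LP is infeasible (a forced uptake loses its only consumer)
  are reported as growth 0 with the status preserved.
* **PhPP** fixes the two scanned uptakes as equalities at each grid point
  (an upper-bound mode is provided; growth is then monotone in each axis).
  Fixtures that are scanned this way need overflow valves — the phototroph
  carries a photon-dissipation sink and a CO₂ escape route; the
  two-substrate fixture carries per-substrate sinks.  Phases are connected
  grid components whose shadow-price pair agrees within 1e−6, zero-growth
  points form their own region, and near-tie points between regions are
  assigned to the lexicographically smaller neighbor and flagged as
  boundary points.

## MOMA reference-vector sensitivity

MOMA is defined relative to a wild-type optimum, and the choice among
degenerate optima matters.  Under light excess the pinned solver returns a
vertex that takes up all available photons and dissipates the surplus
through the cyclic-photophosphorylation/ATPase loop.  Projecting from that
wasteful reference, deleting the cyclic-light gene strands the mutant at
zero growth — the nearest feasible point abandons biomass — although FBA
re-optimization would rescue it.  The screens therefore report, and the
tests assert, that MOMA essentiality is a superset of growth-based (FBA)
essentiality, with such *adjustment-lethal* genes as the difference.  The
wild-type reference vector is stored with every report for reproducibility.

## The synthetic networks and what they do (not) show

`make_toy_phototroph` emulates the study system's structure in 23 reactions:
photon exchange feeding a lumped linear light reaction (ATP + NADPH) and a
cyclic one (ATP only), bicarbonate entry via carbonic anhydrase to CO₂,
a fixation stub (3 CO₂ + 9 ATP + 6 NADPH → one 3-carbon unit), a
hexokinase-style sole glucose entry, chlorophyll synthesis that consumes
photons directly (so dark growth is zero), macromolecule synthesis, and a
biomass reaction assembled from a miniature composition table (protein
0.70 / carbohydrate 0.29 / chromophore 0.01 mass fractions).  Phosphate,
nitrate and sulfate exchanges are present but unconsumed, so the full
trophic presets apply unchanged.  Hand-derived once from the stoichiometry:
9.06 bicarbonate and 31.72 photons per unit biomass autotrophically, hence
growth min(u_HCO3/9.06, u_photon/31.72); mixotrophically
(u_HCO3/3 + 2·u_glc)/3.02.  The structural essential sets are
{gCA, gCfixA, gCfixB, gChl, gCarb} autotrophically and
{gCA, gChl, gCarb, gHex} mixotrophically — carbon-fixation genes are
uniquely autotrophic, the glucose-entry gene uniquely mixotrophic,
mirroring the biology of the study system.

`make_random_network` builds linear pathways feasibility-first (the backbone
carries a known flux vector, so the optimum U/Πcⱼ is exact) and plants
features with recorded truth: parallel interchangeable branches (FVA range
[0, v] each), an orphan metabolite (the only dead end), a sole-path gene
(the only essential), and a two-substrate topology with growth
min(uA/(p·a), uB/(q·b)) whose phase boundary is a line.  Requested sizes
are met exactly by padding with duplicates that inherit the original's GPR
(degeneracy without changing the optimum or the essential set); duplicated
edges are kept irreversible to exclude unbounded internal loops.
`two_substrate` is a dedicated topology and cannot be combined with the
other planted features.

These fixtures exercise every code path with known answers, but they are
small, loop-free by construction, fully mass-consistent and two-compartment;
passing them says nothing about thermodynamic realism, compartmentalized
transport, or the alternate-optima structure of genome-scale models beyond
the degeneracies planted deliberately.

## Deliberate modeling limitations

* No growth-associated ATP maintenance is added to the biomass reaction
  (none is specified for the study system); growth yields are therefore
  upper bounds.
* Elemental balance checking is advisory only and requires formulas, which
  most fixtures omit.
* Transport is free diffusion (orphan transport reactions); no transporter
  genetics, no photoinhibition, no parsimonious/loopless FBA variants.
* Gene rules absent parentheses bind `and` tighter than `or`.

## Problem sizes

The test suite and the acceptance script run on the fixtures above: the
23-reaction phototroph, random networks of 5–11 reactions (small enough for
the exhaustive vertex- and face-enumeration oracles, which scale as
C(n, n−rank)·2ⁿ and 3ⁿ), 11–15-point phase-plane grids for the surface and
finite-difference checks and a 25-point grid in the analysis scripts, and
21 generator seeds for planted-truth recovery.
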