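"""Synthetic constraint-based networks with analytically known ground truth.

Every pipeline stage is testable against these fixtures without any
external model file:

* :func:`make_toy_phototroph` — a ~20-reaction cyanobacterium-style network
  (lumped linear + cyclic light reactions, carbonic anhydrase, a Calvin-
  cycle stub, a glycolytic glucose entry, macromolecule synthesis and a
  composition-assembled biomass) whose optimal growth under autotrophic-,
  heterotrophic- and mixotrophic-style media is known in closed form.
* :func:`make_random_network` — seeded random linear pathways with planted
  features (parallel paths, an orphan metabolite, a sole-path gene, a
  two-substrate topology) and recorded ground truth for each.
* :func:`make_gpr_fixtures` — minimal models exercising AND / OR / nested
  gene rules.

All randomness flows through one ``numpy`` generator per call; the same
seed reproduces byte-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BiomassComposition,
    Compartment,
    MacromoleculeClass,
    MetabolicModel,
    Metabolite,
    Reaction,
    assemble_biomass_reaction,
    INF,
)
from .gpr import parse_gpr
from .io.conditions import ConditionConfig

FEATURES = frozenset({"orphan_metabolite", "sole_path_gene", "parallel_paths", "two_substrate"})


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_metabolites: int = 8
    n_reactions: int = 10
    fraction_reversible: float = 0.2
    gpr_style: str = "simple"  # none | simple | complexes_and_isoenzymes
    features: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.gpr_style not in ("none", "simple", "complexes_and_isoenzymes"):
            raise ValueError(f"unknown gpr_style {self.gpr_style!r}")
        unknown = set(self.features) - FEATURES
        if unknown:
            raise ValueError(f"unknown planted features: {sorted(unknown)}")
        if "two_substrate" in self.features and len(self.features) > 1:
            raise ValueError(
                "two_substrate is a dedicated topology and cannot be combined "
                "with other planted features"
            )


@dataclass
class GroundTruth:
    """Analytic expectations recorded at construction time."""

    growth: dict[str, float] = field(default_factory=dict)
    essential_genes: dict[str, set[str]] = field(default_factory=dict)
    dead_ends: set[str] = field(default_factory=set)
    parallel_fva: dict[str, tuple[float, float]] = field(default_factory=dict)
    conditions: dict[str, ConditionConfig] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# toy phototroph
# ---------------------------------------------------------------------------

# biomass demands per unit growth (from the composition below)
_PROT, _CARB, _CHL = 1.0, 0.5, 0.02
_C3 = 2 * _PROT + 2 * _CARB + 1 * _CHL                  # 3-carbon units
_ATP = 4 * _PROT + 1 * _CARB + 1 * _CHL + 9 * _C3       # incl. fixation cost
_NADPH = 2 * _PROT + 6 * _C3
_HCO3 = 3 * _C3                                         # one carbon per bicarbonate
_PHOTON = _ATP + _CHL                                   # linear + cyclic + chromophore


def toy_biomass_composition() -> BiomassComposition:
    """Miniature macromolecular composition (protein/carbohydrate/chromophore)."""
    return BiomassComposition(
        classes={
            "protein": MacromoleculeClass(0.70, _PROT, {"prot": 1.0}),
            "carbohydrate": MacromoleculeClass(0.29, _CARB, {"carb": 1.0}),
            "antenna chromophore": MacromoleculeClass(0.01, _CHL, {"chl": 1.0}),
        },
        biomass_metabolite_id="biomass",
    )


def toy_conditions() -> dict[str, ConditionConfig]:
    """The three built-in trophic media (the toy accepts the presets as-is)."""
    from .io.conditions import condition_preset

    return {name: condition_preset(name) for name in ("autotrophic", "heterotrophic", "mixotrophic")}


def make_toy_phototroph(seed: int = 0) -> tuple[MetabolicModel, GroundTruth]:
    """The fixed toy phototroph (the seed is accepted for API uniformity only).

    Carbon enters as bicarbonate (dehydrated to CO₂ by carbonic anhydrase)
    or as glucose through a hexokinase-style sole entry; photons drive a
    lumped linear light reaction (ATP + NADPH) and a cyclic one (ATP only);
    chlorophyll synthesis needs photons directly, so dark growth is zero.
    ATPase / NADPH-oxidase valves and a photon-dissipation sink keep
    off-optimum media feasible.  Optimal growth is, in closed form,

        autotrophic:  min(hco3_uptake / 9.06, photon_uptake / 31.72)
        mixotrophic:  (hco3_uptake / 3 + 2 · glc_uptake) / 3.02   (light replete)
    """
    del seed
    cyt = Compartment.CYTOSOL
    ext = Compartment.EXTRACELLULAR
    metabolites = [
        Metabolite("photon", "photon", cyt),
        Metabolite("hco3_e", "bicarbonate (extracellular)", ext),
        Metabolite("hco3", "bicarbonate", cyt),
        Metabolite("co2", "carbon dioxide", cyt),
        Metabolite("glc_e", "alpha-D-glucose (extracellular)", ext),
        Metabolite("glc", "alpha-D-glucose", cyt),
        # medium components the toy does not assimilate (no consumers, so
        # their uptake is balance-forced to zero; they let the full trophic
        # presets apply unchanged)
        Metabolite("pi_e", "phosphate (extracellular)", ext),
        Metabolite("no3_e", "nitrate (extracellular)", ext),
        Metabolite("so4_e", "sulfate (extracellular)", ext),
        Metabolite("atp", "ATP", cyt),
        Metabolite("adp", "ADP", cyt),
        Metabolite("nadph", "NADPH", cyt),
        Metabolite("nadp", "NADP+", cyt),
        Metabolite("c3", "3-carbon intermediate", cyt),
        Metabolite("chl", "chlorophyll a", cyt),
        Metabolite("prot", "protein", cyt),
        Metabolite("carb", "carbohydrate", cyt),
        Metabolite("biomass", "biomass", cyt),
    ]

    def ex(rxn_id: str, met: str) -> Reaction:
        return Reaction(
            id=rxn_id,
            name=rxn_id,
            stoichiometry={met: -1.0},
            reversible=True,
            lower_bound=-INF,
            upper_bound=INF,
            is_exchange=True,
            subsystem="Exchange",
        )

    def rxn(rxn_id, stoich, gpr="", reversible=False, subsystem="Core") -> Reaction:
        return Reaction(
            id=rxn_id,
            name=rxn_id,
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=-INF if reversible else 0.0,
            upper_bound=INF,
            gpr=parse_gpr(gpr),
            subsystem=subsystem,
        )

    biomass = assemble_biomass_reaction(toy_biomass_composition(), reaction_id="BIOMASS")
    reactions = [
        ex("EX_photon", "photon"),
        ex("EX_hco3", "hco3_e"),
        ex("EX_glc", "glc_e"),
        ex("EX_co2", "co2"),
        ex("EX_biomass", "biomass"),
        ex("EX_pi", "pi_e"),
        ex("EX_no3", "no3_e"),
        ex("EX_so4", "so4_e"),
        # photon dissipation sink: equality-fixed light scans stay feasible
        Reaction(
            id="DM_photon",
            name="photon dissipation",
            stoichiometry={"photon": -1.0},
            is_exchange=True,
            subsystem="Exchange",
        ),
        rxn("T_glc", {"glc_e": -1, "glc": 1}, reversible=True, subsystem="Transport"),
        rxn("T_hco3", {"hco3_e": -1, "hco3": 1}, reversible=True, subsystem="Transport"),
        rxn("CA", {"hco3": -1, "co2": 1}, gpr="gCA", reversible=True, subsystem="Carbon uptake"),
        rxn(
            "LIGHT_LINEAR",
            {"photon": -1, "adp": -1, "nadp": -1, "atp": 1, "nadph": 1},
            gpr="gLight1 or gLight2",
            subsystem="Photosynthesis",
        ),
        rxn(
            "LIGHT_CYCLIC",
            {"photon": -1, "adp": -1, "atp": 1},
            gpr="gCyc",
            subsystem="Photosynthesis",
        ),
        rxn(
            "HEX",
            {"glc": -1, "adp": -2, "nadp": -2, "c3": 2, "atp": 2, "nadph": 2},
            gpr="gHex",
            subsystem="Glycolysis",
        ),
        rxn(
            "CFIX",
            {"co2": -3, "atp": -9, "nadph": -6, "c3": 1, "adp": 9, "nadp": 6},
            gpr="gCfixA and gCfixB",
            subsystem="Calvin cycle",
        ),
        rxn(
            "RESP",
            {"c3": -1, "adp": -2, "nadp": -2, "co2": 3, "atp": 2, "nadph": 2},
            gpr="gResp",
            subsystem="Respiration",
        ),
        rxn(
            "CHL_SYN",
            {"c3": -1, "photon": -1, "atp": -1, "chl": 1, "adp": 1},
            gpr="gChl",
            subsystem="Pigment biosynthesis",
        ),
        rxn(
            "PROT_SYN",
            {"c3": -2, "atp": -4, "nadph": -2, "prot": 1, "adp": 4, "nadp": 2},
            gpr="gProtA or gProtB",
            subsystem="Macromolecule synthesis",
        ),
        rxn(
            "CARB_SYN",
            {"c3": -2, "atp": -1, "carb": 1, "adp": 1},
            gpr="gCarb",
            subsystem="Macromolecule synthesis",
        ),
        rxn("ATPASE", {"atp": -1, "adp": 1}, subsystem="Maintenance"),
        rxn("NOX", {"nadph": -1, "nadp": 1}, subsystem="Maintenance"),
        biomass,
    ]
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="BIOMASS",
        id="toy_phototroph",
    )

    conditions = toy_conditions()
    auto = min(0.20 / _HCO3, 100.0 / _PHOTON)
    mixo = (0.20 / 3 + 2 * 0.017) / _C3
    truth = GroundTruth(
        growth={"autotrophic": auto, "heterotrophic": 0.0, "mixotrophic": mixo},
        # growth-based (single-deletion FBA) essential sets; a MOMA screen can
        # additionally flag adjustment-lethal genes whose loss strands the
        # projection from a degenerate wild-type optimum at zero growth
        essential_genes={
            "autotrophic": {"gCA", "gCfixA", "gCfixB", "gChl", "gCarb"},
            "mixotrophic": {"gCA", "gChl", "gCarb", "gHex"},
        },
        dead_ends=set(),
        conditions=conditions,
        extras={
            "hco3_per_biomass": _HCO3,
            "photon_per_biomass": _PHOTON,
            "c3_per_biomass": _C3,
            # hex knockout under mixotrophy: forced glucose uptake has no
            # consumer left, so the mutant is infeasible (reported growth 0);
            # with glucose as an availability (0, 0.017) it grows at the
            # autotrophic rate instead.
            "hex_ko_mixotrophic_fixed": 0.0,
            "hex_ko_mixotrophic_available": auto,
        },
    )
    return model, truth


# ---------------------------------------------------------------------------
# random pathway networks
# ---------------------------------------------------------------------------

_UPTAKE = 10.0


def make_random_network(spec: SyntheticSpec) -> tuple[MetabolicModel, GroundTruth]:
    """A seeded random linear pathway with planted, recorded features.

    Feasibility by construction: the backbone carries the flux vector
    ``v_i = U / Π_{j<=i} c_j`` for uptake ``U``, so the optimum
    ``U / Π c_j`` is known exactly.  Extra reactions requested via
    ``n_reactions`` are duplicates of backbone steps inheriting the
    original's gene rule (degeneracy without changing the optimum or the
    essential set).
    """
    if "two_substrate" in spec.features:
        return _make_two_substrate(spec)
    rng = np.random.default_rng(spec.seed)
    n_extra_mets = 1 if "orphan_metabolite" in spec.features else 0
    k = spec.n_metabolites - n_extra_mets
    if k < 3:
        raise ValueError("need at least 3 backbone metabolites")

    met_ids = [f"m{i}" for i in range(k - 1)] + ["bio"]
    metabolites = [Metabolite(m, m) for m in met_ids]
    coeffs = rng.integers(1, 3, size=k - 1)  # conversion coefficients in {1, 2}

    n_core = (k - 1) + 2  # conversions + EX_in + EX_out
    n_feature = (1 if "parallel_paths" in spec.features else 0) + (
        1 if "orphan_metabolite" in spec.features else 0
    )
    n_pad = spec.n_reactions - n_core - n_feature
    if n_pad < 0:
        raise ValueError(
            f"n_reactions={spec.n_reactions} too small: core+features need {n_core + n_feature}"
        )

    conv_edges = list(range(k - 1))
    parallel_edge = None
    sole_edge = None
    if "parallel_paths" in spec.features:
        parallel_edge = int(rng.integers(0, k - 1))
    if "sole_path_gene" in spec.features:
        candidates = [e for e in conv_edges if e != parallel_edge]
        sole_edge = int(rng.choice(candidates))

    def conv_gpr(edge: int, label: str) -> str:
        if edge == sole_edge:
            return "g_sole"
        if spec.gpr_style == "none":
            return ""
        if spec.gpr_style == "simple" and sole_edge is None:
            return f"g{label}"
        # isoenzyme pairs keep every non-sole gene non-essential
        return f"g{label}a or g{label}b"

    reactions = [
        Reaction(
            id="EX_in",
            name="substrate exchange",
            stoichiometry={"m0": -1.0},
            reversible=True,
            lower_bound=-INF,
            upper_bound=INF,
            is_exchange=True,
        )
    ]
    gpr_of_edge: dict[int, str] = {}
    for e in conv_edges:
        rule = conv_gpr(e, str(e))
        gpr_of_edge[e] = rule
        # duplicated edges stay irreversible: a reversible original next to a
        # forward copy would form an unbounded internal loop; edge 0 is kept
        # irreversible so padding always has a safe target
        reversible = (
            bool(rng.random() < spec.fraction_reversible)
            and e not in (sole_edge, parallel_edge, 0)
        )
        reactions.append(
            Reaction(
                id=f"R{e}",
                name=f"conversion {e}",
                stoichiometry={met_ids[e]: -float(coeffs[e]), met_ids[e + 1]: 1.0},
                reversible=reversible,
                lower_bound=-INF if reversible else 0.0,
                upper_bound=INF,
                gpr=parse_gpr(rule),
            )
        )
    reactions.append(
        Reaction(
            id="EX_bio",
            name="product exchange",
            stoichiometry={"bio": -1.0},
            reversible=False,
            lower_bound=0.0,
            upper_bound=INF,
            is_exchange=True,
        )
    )

    truth = GroundTruth(
        conditions={"default": ConditionConfig("default", {"in": (0.0, _UPTAKE)})}
    )
    products = np.cumprod(coeffs.astype(float))
    optimum = _UPTAKE / float(products[-1])
    truth.growth["default"] = optimum

    if parallel_edge is not None:
        base = reactions[1 + parallel_edge]
        alt = Reaction(
            id=f"R{parallel_edge}_alt",
            name=f"parallel copy of conversion {parallel_edge}",
            stoichiometry=dict(base.stoichiometry),
            reversible=False,
            lower_bound=0.0,
            upper_bound=INF,
        )
        reactions.append(alt)
        # the two interchangeable branches share the edge flux v_edge
        v_edge = _UPTAKE / float(products[parallel_edge])
        truth.parallel_fva[base.id] = (0.0, v_edge)
        truth.parallel_fva[alt.id] = (0.0, v_edge)

    if "orphan_metabolite" in spec.features:
        source = int(rng.integers(0, k - 1))  # never the product itself
        metabolites.append(Metabolite("orphan", "orphan intermediate"))
        reactions.append(
            Reaction(
                id="R_orphan",
                name="leak to orphan intermediate",
                stoichiometry={met_ids[source]: -1.0, "orphan": 1.0},
                reversible=False,
                lower_bound=0.0,
                upper_bound=INF,
            )
        )
        truth.dead_ends = {"orphan"}

    pad_candidates = [
        e for e in conv_edges if e != parallel_edge and not reactions[1 + e].reversible
    ]
    for p in range(n_pad):
        e = pad_candidates[int(rng.integers(0, len(pad_candidates)))]
        base = reactions[1 + e]
        reactions.append(
            Reaction(
                id=f"R{e}_pad{p}",
                name=f"duplicate of conversion {e}",
                stoichiometry=dict(base.stoichiometry),
                reversible=False,
                lower_bound=0.0,
                upper_bound=INF,
                gpr=parse_gpr(gpr_of_edge[e]),  # same rule: essentiality unchanged
            )
        )

    if sole_edge is not None:
        truth.essential_genes["default"] = {"g_sole"}
    elif spec.gpr_style == "simple":
        truth.essential_genes["default"] = {
            f"g{e}" for e in conv_edges if e != parallel_edge
        }

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="EX_bio",
        id=f"random_{spec.seed}",
    )
    return model, truth


def _make_two_substrate(spec: SyntheticSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Two substrates with analytic min-form growth for phase-plane tests.

    Substrate A converts (p:1) to precursor C, substrate B (q:1) to
    precursor E; biomass drains a·C + b·E.  With uptakes (uA, uB):

        growth = min(uA / (p·a), uB / (q·b))

    Overflow sinks for A and B keep equality-fixed scans feasible.
    """
    rng = np.random.default_rng(spec.seed)
    p, q = (int(x) for x in rng.integers(1, 4, size=2))
    a, b = (int(x) for x in rng.integers(1, 3, size=2))
    metabolites = [Metabolite(m, m) for m in ["A", "B", "C", "E", "bio"]]
    reactions = [
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, reversible=True,
                 lower_bound=-INF, upper_bound=INF, is_exchange=True),
        Reaction(id="EX_B", stoichiometry={"B": -1.0}, reversible=True,
                 lower_bound=-INF, upper_bound=INF, is_exchange=True),
        Reaction(id="DM_A", name="overflow sink for A",
                 stoichiometry={"A": -1.0}, is_exchange=True),
        Reaction(id="DM_B", name="overflow sink for B",
                 stoichiometry={"B": -1.0}, is_exchange=True),
        Reaction(id="CONV_A", stoichiometry={"A": -float(p), "C": 1.0}),
        Reaction(id="CONV_B", stoichiometry={"B": -float(q), "E": 1.0}),
        Reaction(id="BIOMASS", stoichiometry={"C": -float(a), "E": -float(b), "bio": 1.0}),
        Reaction(id="EX_bio", stoichiometry={"bio": -1.0}, is_exchange=True),
    ]
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="BIOMASS",
        id=f"two_substrate_{spec.seed}",
    )
    cost_a, cost_b = float(p * a), float(q * b)
    truth = GroundTruth(
        growth={"default": min(_UPTAKE / cost_a, _UPTAKE / cost_b)},
        conditions={
            "default": ConditionConfig("default", {"A": (0.0, _UPTAKE), "B": (0.0, _UPTAKE)})
        },
        extras={"cost_a": cost_a, "cost_b": cost_b},
    )
    return model, truth


# ---------------------------------------------------------------------------
# GPR fixtures
# ---------------------------------------------------------------------------


def make_gpr_fixtures() -> list[tuple[MetabolicModel, GroundTruth]]:
    """Minimal models for complex / isoenzyme / nested / orphan gene rules.

    Each fixture is a one-step pathway whose sole conversion carries the
    rule of interest; growth is 1 when the rule evaluates true and 0 (by
    disabled reaction) when false.  ``extras`` is empty; the rule text is
    recoverable from the conversion's GPR for truth-table enumeration.
    """
    rules = {
        "complex": "gA and gB",
        "isoenzymes": "gA or gB",
        "nested": "(gA and gB) or gC",
        "orphan": "",
    }
    fixtures = []
    for label, rule in rules.items():
        metabolites = [Metabolite("s", "s"), Metabolite("p", "p")]
        reactions = [
            Reaction(id="EX_s", stoichiometry={"s": -1.0}, reversible=True,
                     lower_bound=-INF, upper_bound=INF, is_exchange=True),
            Reaction(id="CONV", stoichiometry={"s": -1.0, "p": 1.0}, gpr=parse_gpr(rule)),
            Reaction(id="EX_p", stoichiometry={"p": -1.0}, is_exchange=True),
        ]
        model = MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction_id="EX_p",
            id=f"gpr_{label}",
        )
        truth = GroundTruth(
            growth={"default": 1.0},
            conditions={"default": ConditionConfig("default", {"s": (0.0, 1.0)})},
        )
        fixtures.append((model, truth))
    return fixtures
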