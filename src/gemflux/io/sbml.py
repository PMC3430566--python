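"""SBML Level-2 reader/writer in the legacy COBRA dialect.

The dialect predates the fbc package: flux bounds live in per-reaction
kinetic-law parameters named ``LOWER_BOUND`` / ``UPPER_BOUND``, the
objective in ``OBJECTIVE_COEFFICIENT``, and the gene rule in an HTML note
``GENE_ASSOCIATION: ...``.  Species with ``boundaryCondition="true"`` (or a
``_b`` id suffix) are boundary copies that only open the system.

Unbounded fluxes are serialized as ±999999 (the convention of that era's
model files) and mapped back to ±inf on read.  Exchange reactions written
as a single species gain a ``<id>_b`` boundary partner on write; the
partner is stripped again on read, so write∘read is the identity on
structure, bounds, and gene rules.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import libsbml

from ..core import Compartment, MetabolicModel, Metabolite, Reaction, INF
from ..gpr import GPRParseError, parse_gpr

logger = logging.getLogger(__name__)

BOUND_CAP = 999999.0

_COMPARTMENT_IDS = {
    Compartment.CYTOSOL: "c",
    Compartment.EXTRACELLULAR: "e",
    Compartment.BOUNDARY: "b",
}
_COMPARTMENT_FROM_ID = {v: k for k, v in _COMPARTMENT_IDS.items()}

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, taken: dict[str, str]) -> str:
    """Deterministic SBML-id sanitization; original text goes to the name slot."""
    sid = _SID_RE.sub("_", raw)
    if not sid or sid[0].isdigit():
        sid = "_" + sid
    base, n = sid, 1
    while sid in taken and taken[sid] != raw:
        n += 1
        sid = f"{base}_{n}"
    taken[sid] = raw
    return sid


def _cap(value: float) -> float:
    if value == INF:
        return BOUND_CAP
    if value == -INF:
        return -BOUND_CAP
    return value


def _uncap(value: float) -> float:
    if value >= BOUND_CAP:
        return INF
    if value <= -BOUND_CAP:
        return -INF
    return value


def write_sbml_cobra(model: MetabolicModel, path: str | Path) -> None:
    document = libsbml.SBMLDocument(2, 1)
    smodel = document.createModel()
    smodel.setId(_SID_RE.sub("_", model.id) or "model")

    for compartment in Compartment:
        c = smodel.createCompartment()
        c.setId(_COMPARTMENT_IDS[compartment])
        c.setName(compartment.value)
        c.setSize(1.0)

    taken: dict[str, str] = {}
    sid_of: dict[str, str] = {}
    for met in model.metabolites:
        sid_of[met.id] = _sid(met.id, taken)
    for met in model.metabolites:
        s = smodel.createSpecies()
        s.setId(sid_of[met.id])
        s.setName(met.id)
        s.setCompartment(_COMPARTMENT_IDS[met.compartment])
        s.setBoundaryCondition(met.compartment is Compartment.BOUNDARY)
        s.setInitialAmount(0.0)

    rxn_taken: dict[str, str] = {}
    for rxn in model.reactions:
        r = smodel.createReaction()
        r.setId(_sid(rxn.id, rxn_taken))
        r.setName(rxn.id)
        r.setReversible(rxn.reversible)

        stoich = dict(rxn.stoichiometry)
        has_boundary_partner = any(
            model.metabolite(m).compartment is Compartment.BOUNDARY for m in stoich
        )
        if rxn.is_exchange and not has_boundary_partner and len(stoich) == 1:
            (met_id, coeff), = stoich.items()
            partner = f"{sid_of[met_id]}_b"
            if smodel.getSpecies(partner) is None:
                s = smodel.createSpecies()
                s.setId(partner)
                s.setName(partner)
                s.setCompartment(_COMPARTMENT_IDS[Compartment.BOUNDARY])
                s.setBoundaryCondition(True)
                s.setInitialAmount(0.0)
            stoich[partner] = -coeff  # export direction: internal -> boundary

        for met_id, coeff in stoich.items():
            sid = sid_of.get(met_id, met_id)
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(coeff))

        notes = [f"<p>GENE_ASSOCIATION: {rxn.gpr.to_string()}</p>"]
        if rxn.subsystem:
            notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
        r.setNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(notes) + "</body>"
        )

        law = r.createKineticLaw()
        law.setFormula("FLUX_VALUE")
        for pname, pvalue in (
            ("LOWER_BOUND", _cap(rxn.lower_bound)),
            ("UPPER_BOUND", _cap(rxn.upper_bound)),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.id == model.objective_reaction_id else 0.0),
            ("FLUX_VALUE", 0.0),
        ):
            p = law.createParameter()
            p.setId(pname)
            p.setValue(pvalue)

    libsbml.writeSBMLToFile(document, str(path))
    logger.info("wrote SBML model %s (%d reactions) to %s", model.id, len(model.reactions), path)


def _note_field(notes_text: str, key: str) -> str | None:
    match = re.search(rf"{key}\s*:\s*([^<\n]*)", notes_text)
    return match.group(1).strip() if match else None


def read_sbml_cobra(path: str | Path) -> MetabolicModel:
    document = libsbml.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"SBML parse errors in {path}: "
            + "; ".join(
                document.getError(i).getMessage()
                for i in range(document.getNumErrors())
            )
        )
    smodel = document.getModel()
    if smodel is None:
        raise ValueError(f"no model element in {path}")

    compartment_kind: dict[str, Compartment] = {}
    for i in range(smodel.getNumCompartments()):
        c = smodel.getCompartment(i)
        kind = _COMPARTMENT_FROM_ID.get(c.getId())
        if kind is None:
            name = (c.getName() or "").lower()
            kind = next(
                (k for k in Compartment if k.value.startswith(name[:5]) and name),
                Compartment.CYTOSOL,
            )
        compartment_kind[c.getId()] = kind

    original_id: dict[str, str] = {}
    metabolites: dict[str, Metabolite] = {}
    boundary_sids: set[str] = set()
    for i in range(smodel.getNumSpecies()):
        s = smodel.getSpecies(i)
        sid = s.getId()
        met_id = s.getName() or sid
        original_id[sid] = met_id
        compartment = compartment_kind.get(s.getCompartment(), Compartment.CYTOSOL)
        if s.getBoundaryCondition() or sid.endswith("_b"):
            compartment = Compartment.BOUNDARY
            boundary_sids.add(sid)
        metabolites[sid] = Metabolite(id=met_id, name=met_id, compartment=compartment)

    # boundary partners auto-added on write are stripped back out
    strippable = {sid for sid in boundary_sids if sid.endswith("_b")}

    reactions: list[Reaction] = []
    objective_id = ""
    used_sids: set[str] = set()
    for i in range(smodel.getNumReactions()):
        r = smodel.getReaction(i)
        rxn_id = r.getName() or r.getId()
        stoich: dict[str, float] = {}
        touches_boundary = False
        for ref, sign in [
            (r.getReactant(j), -1.0) for j in range(r.getNumReactants())
        ] + [(r.getProduct(j), +1.0) for j in range(r.getNumProducts())]:
            sid = ref.getSpecies()
            if sid in boundary_sids:
                touches_boundary = True
            if sid in strippable:
                continue
            met_id = original_id.get(sid, sid)
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * ref.getStoichiometry()
            used_sids.add(sid)

        reversible = r.getReversible()
        lower, upper, objective_coeff = None, None, 0.0
        law = r.getKineticLaw()
        if law is not None:
            for j in range(law.getNumParameters()):
                p = law.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lower = _uncap(p.getValue())
                elif p.getId() == "UPPER_BOUND":
                    upper = _uncap(p.getValue())
                elif p.getId() == "OBJECTIVE_COEFFICIENT":
                    objective_coeff = p.getValue()
        if lower is None or upper is None:
            logger.warning(
                "reaction %s in %s is missing bound parameters; applying dialect defaults",
                rxn_id,
                path,
            )
            if lower is None:
                lower = -INF if reversible else 0.0
            if upper is None:
                upper = INF
        if objective_coeff != 0.0:
            objective_id = rxn_id

        gpr_text = _note_field(r.getNotesString() or "", "GENE_ASSOCIATION")
        try:
            gpr = parse_gpr(gpr_text or "")
        except GPRParseError as exc:
            logger.warning("reaction %s: malformed GPR (%s); treating as orphan", rxn_id, exc)
            gpr = parse_gpr("")
        subsystem = _note_field(r.getNotesString() or "", "SUBSYSTEM") or ""

        reactions.append(
            Reaction(
                id=rxn_id,
                name=r.getName() or rxn_id,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
                subsystem=subsystem,
                is_exchange=touches_boundary or len(stoich) == 1,
            )
        )

    kept = [
        met
        for sid, met in metabolites.items()
        if sid not in strippable or sid in used_sids
    ]
    model = MetabolicModel(
        metabolites=kept,
        reactions=reactions,
        objective_reaction_id=objective_id,
        id=smodel.getId() or Path(path).stem,
    )
    logger.info(
        "read SBML model %s: %d reactions, %d metabolites", model.id, len(reactions), len(kept)
    )
    return model
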