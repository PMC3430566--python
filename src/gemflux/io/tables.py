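"""Delimited reaction-table reader/writer.

The table dialect has one reaction per row with columns
``id, name, equation, pathway, genes`` (tab- or comma-delimited, header
optional but written by default).  Stoichiometry comes from the equation
string; the gene column holds a boolean rule with ``and``/``or`` and
parentheses (empty cell = orphan reaction).

Compartments are inferred from the legacy species-name suffixes used in
this dialect: ``...XTX`` marks the boundary copy of a species (exists only
to open the system), ``...XT`` the extracellular copy, anything else is
cytosolic.  A reaction touching a boundary species — or consisting of a
single species — is an exchange reaction.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from ..core import Compartment, MetabolicModel, Metabolite, Reaction, INF
from ..gpr import parse_gpr
from .equations import format_reaction_equation, parse_reaction_equation

logger = logging.getLogger(__name__)

_HEADER = ["id", "name", "equation", "pathway", "genes"]


def _compartment_for(species: str) -> Compartment:
    if species.endswith("XTX") or species.endswith("_b"):
        return Compartment.BOUNDARY
    if species.endswith("XT") or species.endswith("_e"):
        return Compartment.EXTRACELLULAR
    return Compartment.CYTOSOL


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if "\t" in first or "," not in first else ","


def read_reaction_table(path: str | Path, objective_reaction_id: str = "") -> MetabolicModel:
    """Parse a delimited reaction table into a model.

    Bounds are assigned from reversibility: reversible -> (-inf, +inf),
    irreversible -> (0, +inf).  Raises ValueError naming the row on a
    malformed line.
    """
    path = Path(path)
    text = path.read_text()
    rows = [r for r in csv.reader(text.splitlines(), delimiter=_sniff_delimiter(text))]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if rows and [c.strip().lower() for c in rows[0][:2]] == _HEADER[:2]:
        rows = rows[1:]

    reactions: list[Reaction] = []
    met_compartments: dict[str, Compartment] = {}
    for rowno, row in enumerate(rows, start=1):
        if len(row) < 3:
            raise ValueError(f"{path}: row {rowno}: expected at least 3 columns, got {len(row)}")
        rxn_id, name, equation = (c.strip() for c in row[:3])
        pathway = row[3].strip() if len(row) > 3 else ""
        gene_cell = row[4].strip() if len(row) > 4 else ""
        try:
            stoich, reversible = parse_reaction_equation(equation)
            gpr = parse_gpr(gene_cell)
        except ValueError as exc:
            raise ValueError(f"{path}: row {rowno} ({rxn_id}): {exc}") from exc
        for species in stoich:
            met_compartments.setdefault(species, _compartment_for(species))
        is_exchange = len(stoich) == 1 or any(
            _compartment_for(s) is Compartment.BOUNDARY for s in stoich
        )
        reactions.append(
            Reaction(
                id=rxn_id,
                name=name,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=-INF if reversible else 0.0,
                upper_bound=INF,
                gpr=gpr,
                subsystem=pathway,
                is_exchange=is_exchange,
            )
        )
    metabolites = [
        Metabolite(id=m, name=m, compartment=c) for m, c in sorted(met_compartments.items())
    ]
    logger.info("read %d reactions / %d metabolites from %s", len(reactions), len(metabolites), path)
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_reaction_id,
        id=path.stem,
    )


def write_reaction_table(model: MetabolicModel, path: str | Path, delimiter: str = "\t") -> None:
    """Write the model as a delimited reaction table (inverse of the reader)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(_HEADER)
        for rxn in model.reactions:
            writer.writerow(
                [
                    rxn.id,
                    rxn.name,
                    format_reaction_equation(dict(rxn.stoichiometry), rxn.reversible),
                    rxn.subsystem,
                    rxn.gpr.to_string(),
                ]
            )
    logger.info("wrote %d reactions to %s", len(model.reactions), path)
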