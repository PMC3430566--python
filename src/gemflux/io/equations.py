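"""Parsing of textual reaction equations.

Reaction tables describe stoichiometry as strings like

    Alpha-D-glucose + ATP -- > alpha-D-glucose-6-phosphate + ADP + H+

The arrow token decides reversibility.  Several ASCII and unicode variants
of the arrows circulate in legacy tables and are all accepted.  Species are
separated by `` + `` (plus with surrounding whitespace, so names like
``H+`` survive) and may carry a leading numeric coefficient (default 1).
"""

from __future__ import annotations

import re
import warnings

# ordered longest-first so "< -- >" wins over "-- >"
_REVERSIBLE_ARROWS = ["< −− >", "<−−>", "< -- >", "<-->", "<==>", "<=>", "<->", "↔"]
_IRREVERSIBLE_ARROWS = ["−− >", "−−>", "-- >", "-->", "==>", "=>", "->", "→"]


class EquationParseError(ValueError):
    """Raised for malformed equation strings; message carries the position."""


def _find_arrow(text: str) -> tuple[int, int, bool]:
    """Locate the single arrow token; returns (start, end, reversible)."""
    hits: list[tuple[int, int, bool]] = []
    for reversible, arrows in ((True, _REVERSIBLE_ARROWS), (False, _IRREVERSIBLE_ARROWS)):
        for arrow in arrows:
            start = 0
            while True:
                i = text.find(arrow, start)
                if i < 0:
                    break
                hits.append((i, i + len(arrow), reversible))
                start = i + len(arrow)
    if not hits:
        raise EquationParseError(f"no arrow token in equation: {text!r}")
    # drop irreversible hits contained in a reversible hit (e.g. "-->" inside "<-->")
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    filtered: list[tuple[int, int, bool]] = []
    for h in hits:
        if filtered and h[0] < filtered[-1][1]:
            continue
        filtered.append(h)
    if len(filtered) > 1:
        raise EquationParseError(
            f"multiple arrow tokens (positions {[h[0] for h in filtered]}) in equation: {text!r}"
        )
    return filtered[0]


_COEFF_RE = re.compile(r"^(\d+(?:\.\d+)?|\.\d+)\s+(.+)$")


def _parse_side(side: str, sign: float, stoich: dict[str, float], position: int, text: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in re.split(r"\s\+\s", side):
        term = term.strip()
        if not term:
            raise EquationParseError(
                f"empty species term near position {position} in equation: {text!r}"
            )
        m = _COEFF_RE.match(term)
        if m:
            coeff, name = float(m.group(1)), m.group(2).strip()
        else:
            coeff, name = 1.0, term
        # duplicate species on one side (or across sides) accumulate
        stoich[name] = stoich.get(name, 0.0) + sign * coeff


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry map, reversible flag).

    Species occurring on both sides accumulate; a species with net-zero
    coefficient is kept in the map (with value 0.0) and triggers a warning.
    """
    if not text or not text.strip():
        raise EquationParseError("empty equation string")
    start, end, reversible = _find_arrow(text)
    lhs, rhs = text[:start], text[end:]
    if not lhs.strip() and not reversible:
        raise EquationParseError(
            f"irreversible reaction with empty substrate side at position 0: {text!r}"
        )
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich, 0, text)
    _parse_side(rhs, +1.0, stoich, end, text)
    for name, coeff in stoich.items():
        if coeff == 0.0:
            warnings.warn(
                f"species {name!r} has net-zero stoichiometry in equation: {text!r}",
                stacklevel=2,
            )
    return stoich, reversible


def _format_coeff(c: float) -> str:
    if c == int(c):
        c = int(c)
        return "" if c == 1 else f"{c} "
    return f"{c:g} "


def format_reaction_equation(stoichiometry: dict[str, float], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (canonical ASCII arrows)."""
    lhs = " + ".join(
        f"{_format_coeff(-c)}{name}" for name, c in stoichiometry.items() if c < 0
    )
    rhs = " + ".join(
        f"{_format_coeff(c)}{name}" for name, c in stoichiometry.items() if c > 0
    )
    arrow = "<-->" if reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()
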