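"""Gene-protein-reaction (GPR) boolean rules.

A reaction's availability is described by a boolean expression over gene
identifiers: AND joins subunits of an enzyme complex (all are required),
OR joins isoenzymes (any one suffices).  An empty expression means the
reaction has no gene association and can never be disabled by a knockout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


class GPRParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids.

    ``op`` is ``"gene"`` (leaf, ``value`` holds the id), ``"and"``, ``"or"``,
    or ``"empty"`` for no gene association.  ``children`` holds sub-expressions
    for the two connective kinds.
    """

    op: str = "empty"
    value: str = ""
    children: tuple["GPRExpression", ...] = field(default_factory=tuple)

    # -- constructors -------------------------------------------------

    @staticmethod
    def empty() -> "GPRExpression":
        return GPRExpression()

    @staticmethod
    def gene(gene_id: str) -> "GPRExpression":
        if not gene_id:
            raise GPRParseError("gene leaf must be a non-empty id")
        return GPRExpression(op="gene", value=gene_id)

    @staticmethod
    def all_of(*exprs: "GPRExpression") -> "GPRExpression":
        return GPRExpression(op="and", children=tuple(exprs))

    @staticmethod
    def any_of(*exprs: "GPRExpression") -> "GPRExpression":
        return GPRExpression(op="or", children=tuple(exprs))

    # -- queries ------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        """All gene ids appearing as leaves."""
        return set(self._iter_leaves())

    def _iter_leaves(self) -> Iterator[str]:
        if self.op == "gene":
            yield self.value
        else:
            for child in self.children:
                yield from child._iter_leaves()

    def evaluate(self, knocked: set[str] | frozenset[str] = frozenset()) -> bool:
        """Truth value when the genes in ``knocked`` are absent.

        Empty expressions always evaluate True: reactions with no gene
        association are never disabled by a deletion.
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            return self.value not in knocked
        if self.op == "and":
            return all(c.evaluate(knocked) for c in self.children)
        if self.op == "or":
            return any(c.evaluate(knocked) for c in self.children)
        raise AssertionError(f"unknown GPR node {self.op!r}")

    def to_string(self) -> str:
        """Canonical rule text, e.g. ``"(g1 and g2) or g3"``."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.value
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize any nested connective so precedence is explicit
            if child.op in ("and", "or"):
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRExpression:
    """Parse a rule string like ``"(g1 and g2) or g3"``.

    ``and`` binds tighter than ``or``; both keywords are case-insensitive.
    An empty or whitespace-only string yields the empty expression.
    """
    tokens = _TOKEN_RE.findall(text or "")
    if not tokens:
        return GPRExpression.empty()
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRExpression.any_of(*terms)

    def parse_and() -> GPRExpression:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPRExpression.all_of(*factors)

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in GPR rule: {text!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR rule: {text!r}")
        return GPRExpression.gene(take())

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule: {text!r}")
    return expr
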