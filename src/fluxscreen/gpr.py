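"""Gene–protein–reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers built from
``and`` (enzyme complexes: every subunit required) and ``or``
(isoenzymes: any one gene suffices), with parentheses for grouping.
A reaction whose rule evaluates to ``False`` under a gene-deletion
assignment cannot carry flux; a reaction with an empty rule is never
disabled by gene deletions.

The parser is a small recursive-descent implementation with the usual
precedence (``and`` binds tighter than ``or``).  It is deliberately
self-contained so that tests can cross-check it against an external
evaluator without circularity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

__all__ = ["Gpr", "GprParseError", "parse_gpr"]

# AST nodes: a bare gene id (str), or ("and"|"or", [children...])
Node = Union[str, tuple]

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")
_KEYWORDS = {"and": "and", "&": "and", "&&": "and",
             "or": "or", "|": "or", "||": "or"}


class GprParseError(ValueError):
    """Raised when a gene-rule string cannot be parsed."""


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:  # only trailing whitespace remains
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprParseError(f"unexpected end of gene rule: {self.text!r}")
        self.pos += 1
        return tok

    def parse_expr(self) -> Node:
        terms = [self.parse_term()]
        while self.peek() is not None and _KEYWORDS.get(self.peek().lower()) == "or":
            self.next()
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_term(self) -> Node:
        factors = [self.parse_factor()]
        while self.peek() is not None and _KEYWORDS.get(self.peek().lower()) == "and":
            self.next()
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_factor(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.parse_expr()
            if self.next() != ")":
                raise GprParseError(f"unbalanced parentheses in gene rule: {self.text!r}")
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GprParseError(f"unexpected {tok!r} in gene rule: {self.text!r}")
        return tok


def _atoms(node: Node, out: set[str]) -> None:
    if isinstance(node, str):
        out.add(node)
    else:
        for child in node[1]:
            _atoms(child, out)


def _evaluate(node: Node, knocked_out: frozenset[str]) -> bool:
    if isinstance(node, str):
        return node not in knocked_out
    op, children = node
    if op == "and":
        return all(_evaluate(c, knocked_out) for c in children)
    return any(_evaluate(c, knocked_out) for c in children)


def _to_string(node: Node, parent_op: str | None = None) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    inner = f" {op} ".join(_to_string(c, op) for c in children)
    # parenthesize an 'or' nested under an 'and' to keep precedence explicit
    if parent_op == "and" and op == "or":
        return f"({inner})"
    return inner


@dataclass(frozen=True)
class Gpr:
    """A parsed gene rule.  ``Gpr(None)`` is the empty (always-true) rule."""

    root: Node | None

    @property
    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing in the rule."""
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        _atoms(self.root, out)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """Whether the reaction remains catalysable with ``knocked_out`` deleted.

        Every gene not listed in ``knocked_out`` is considered present.
        The empty rule always evaluates to ``True``: spontaneous or
        orphan reactions survive any knockout.
        """
        if self.root is None:
            return True
        return _evaluate(self.root, frozenset(knocked_out))

    def to_string(self) -> str:
        return "" if self.root is None else _to_string(self.root)

    def __bool__(self) -> bool:
        return self.root is not None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str | None) -> Gpr:
    """Parse a gene-rule string into a :class:`Gpr`.

    Accepts ``and``/``or`` (any case) plus the ``&``/``|`` spellings and
    parentheses.  An empty or whitespace-only string yields the empty rule.
    """
    if text is None or not text.strip():
        return Gpr(None)
    parser = _Parser(_tokenize(text), text)
    node = parser.parse_expr()
    if parser.peek() is not None:
        raise GprParseError(f"trailing tokens in gene rule: {text!r}")
    return Gpr(node)
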