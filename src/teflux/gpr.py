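"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule such as ``"(g1 and g2) or g3"`` states which gene combinations
enable a reaction: AND joins subunits of a complex, OR joins isozymes.  Rules
are parsed into a small boolean tree that can be evaluated against any
gene-presence assignment; this is what the isozyme screen rests on (a gene is
*buffered* when every rule it appears in stays true without it).
"""

from __future__ import annotations

import re
from collections.abc import Callable, Iterable
from dataclasses import dataclass

__all__ = ["GPRExpression", "GPRSyntaxError", "parse_gpr"]


class GPRSyntaxError(ValueError):
    """Malformed GPR rule; carries the offending position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


# -- tree nodes -------------------------------------------------------------

@dataclass(frozen=True)
class _Gene:
    name: str

    def evaluate(self, present: Callable[[str], bool]) -> bool:
        return present(self.name)

    def genes(self) -> frozenset[str]:
        return frozenset((self.name,))

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class _Op:
    op: str  # "and" | "or"
    children: tuple

    def evaluate(self, present: Callable[[str], bool]) -> bool:
        it = (c.evaluate(present) for c in self.children)
        return all(it) if self.op == "and" else any(it)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        sep = f" {self.op} "
        return "(" + sep.join(c.to_string() for c in self.children) + ")"


class GPRExpression:
    """A parsed GPR rule.  The empty expression (no gene requirement) is
    always satisfied."""

    def __init__(self, root=None) -> None:
        self._root = root

    @classmethod
    def empty(cls) -> "GPRExpression":
        return cls(None)

    @property
    def is_empty(self) -> bool:
        return self._root is None

    def genes(self) -> frozenset[str]:
        return frozenset() if self._root is None else self._root.genes()

    def evaluate(self, present: Iterable[str] | Callable[[str], bool]) -> bool:
        """Evaluate against *present*: a collection of present genes, or a
        predicate.  Empty rules evaluate true."""
        if self._root is None:
            return True
        if callable(present):
            return self._root.evaluate(present)
        present_set = frozenset(present)
        return self._root.evaluate(present_set.__contains__)

    def satisfied_without(self, gene: str) -> bool:
        """Rule value when *gene* is absent and every other gene is present."""
        return self.evaluate(lambda g: g != gene)

    def to_string(self) -> str:
        return "" if self._root is None else self._root.to_string()

    def __eq__(self, other) -> bool:
        return isinstance(other, GPRExpression) and self._root == other._root

    def __hash__(self) -> int:
        return hash(self._root)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GPRExpression({self.to_string()!r})"


# -- parser -----------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule_text: str) -> GPRExpression:
    """Parse a boolean gene rule with ``and``/``or`` (case-insensitive) and
    parentheses.  ``and`` binds tighter than ``or``; the empty string yields
    the empty expression.

    Raises :class:`GPRSyntaxError` on unbalanced parentheses or dangling
    operators, naming the character position.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        return GPRExpression.empty()
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(rule_text))

    def parse_or():
        nonlocal idx
        terms = [parse_and()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            idx += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else _Op("or", tuple(terms))

    def parse_and():
        nonlocal idx
        factors = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            idx += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else _Op("and", tuple(factors))

    def parse_atom():
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GPRSyntaxError("dangling operator: expected gene or '('", pos)
        if tok == "(":
            idx += 1
            node = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRSyntaxError("unbalanced parentheses: expected ')'", pos2)
            idx += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r}", pos)
        idx += 1
        return _Gene(tok)

    root = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GPRSyntaxError(f"unexpected trailing token {tok!r}", pos)
    return GPRExpression(root)
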