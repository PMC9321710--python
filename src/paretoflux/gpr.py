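"""Gene-protein-reaction (GPR) rules.

A GPR rule is a Boolean expression over gene identifiers that gates a
reaction: AND joins enzyme subunits (all required), OR joins isoenzymes
(any one suffices).  Rules are parsed from the conventional string form
(``"(g1 and g2) or g3"``) into a small expression tree and evaluated
against a gene-state assignment (1 = present, 0 = knocked out).

Grammar (AND binds tighter than OR, operators case-insensitive)::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := GENE | "(" expr ")"
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "GPRRule",
    "Literal",
    "And",
    "Or",
    "GPRParseError",
    "parse_gpr",
    "evaluate_gpr",
]


class GPRParseError(ValueError):
    """Raised when a GPR string is malformed; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRRule:
    """Base class for GPR expression-tree nodes."""

    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing in the rule."""
        return frozenset(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def evaluate(self, states: Mapping[str, int]) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class Literal(GPRRule):
    gene: str

    def _iter_genes(self) -> Iterator[str]:
        yield self.gene

    def evaluate(self, states: Mapping[str, int]) -> bool:
        try:
            return bool(states[self.gene])
        except KeyError:
            raise KeyError(f"no state supplied for gene {self.gene!r}") from None

    def __repr__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class And(GPRRule):
    children: tuple[GPRRule, ...]

    def _iter_genes(self) -> Iterator[str]:
        for child in self.children:
            yield from child._iter_genes()

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return all(c.evaluate(states) for c in self.children)

    def __repr__(self) -> str:
        return "(" + " and ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Or(GPRRule):
    children: tuple[GPRRule, ...]

    def _iter_genes(self) -> Iterator[str]:
        for child in self.children:
            yield from child._iter_genes()

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return any(c.evaluate(states) for c in self.children)

    def __repr__(self) -> str:
        return "(" + " or ".join(map(repr, self.children)) + ")"


_SPECIAL = {"(", ")"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (kind, value, position) triples.

    Identifiers are any maximal run of characters that is not whitespace or
    a parenthesis; ``and``/``or`` (case-insensitive) become operators.
    """
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _SPECIAL:
            tokens.append((ch, ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in _SPECIAL:
            j += 1
        word = text[i:j]
        low = word.lower()
        if low == "and":
            tokens.append(("AND", word, i))
        elif low == "or":
            tokens.append(("OR", word, i))
        else:
            tokens.append(("GENE", word, i))
        i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int] | None:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GPRRule:
        if not self.tokens:
            raise GPRParseError("empty GPR string", 0)
        rule = self.expr()
        trailing = self.peek()
        if trailing is not None:
            raise GPRParseError(f"unexpected token {trailing[1]!r}", trailing[2])
        return rule

    def expr(self) -> GPRRule:
        terms = [self.term()]
        while (tok := self.peek()) is not None and tok[0] == "OR":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> GPRRule:
        factors = [self.factor()]
        while (tok := self.peek()) is not None and tok[0] == "AND":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> GPRRule:
        tok = self.next()
        if tok is None:
            raise GPRParseError("dangling operator", len(self.text))
        kind, value, pos = tok
        if kind == "GENE":
            return Literal(value)
        if kind == "(":
            inner = self.expr()
            closing = self.next()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parentheses", pos)
            return inner
        raise GPRParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    AND binds tighter than OR, so ``"g1 or g2 and g3"`` parses as
    ``Or(g1, And(g2, g3))``.  Parentheses override precedence.

    Raises
    ------
    GPRParseError
        On empty input, unbalanced parentheses, or dangling operators; the
        exception carries the offending character position.
    """
    return _Parser(text).parse()


def evaluate_gpr(rule: GPRRule, states: Mapping[str, int]) -> bool:
    """Evaluate a rule under a gene-state assignment.

    Returns True when the gated reaction remains active.  Every gene
    appearing in the rule must have a state; a missing gene raises
    ``KeyError`` naming it.
    """
    return rule.evaluate(states)
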