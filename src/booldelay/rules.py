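"""Transfer-rule data model and the text grammar for delayed Boolean rules.

A rule is a gate tree (AND / OR / NOT) whose leaves are lagged, parameterized
input terms written as ``r*SOURCE(t-theta)``:

* ``theta`` (the lag, minutes >= 1) is the delayed-activation time: the source
  must have been ON continuously for ``theta`` minutes before the term's gate
  can open.
* ``r`` (the integer coefficient, nonzero) is the sustain/delay parameter:
  ``r >= 1`` means the gate output is sustained after the input lapses,
  ``r <= -1`` means the gate needs ``|r|`` additional minutes of accumulated
  activation before it opens.  An absent coefficient means ``r = 1``.

Operator precedence is NOT > AND > OR; parentheses group subexpressions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

__all__ = [
    "EdgeTerm",
    "Leaf",
    "Not",
    "And",
    "Or",
    "Expression",
    "TransferRule",
    "RuleParseError",
    "parse_rule",
    "format_expression",
]


class RuleParseError(ValueError):
    """Raised when a rule string does not match the grammar."""


@dataclass(frozen=True)
class EdgeTerm:
    """One lagged input term of a transfer rule (one edge of the network)."""

    source: str
    theta: int
    r: int
    negated: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.theta, int) or isinstance(self.theta, bool):
            raise ValueError(f"theta must be an integer, got {self.theta!r}")
        if not isinstance(self.r, int) or isinstance(self.r, bool):
            raise ValueError(f"r must be an integer, got {self.r!r}")
        if self.theta < 1:
            raise ValueError(
                f"term {self.source!r}: activation delay theta must be >= 1, "
                f"got {self.theta}"
            )
        if self.r == 0:
            raise ValueError(f"term {self.source!r}: r must be nonzero")


@dataclass(frozen=True)
class Leaf:
    term: EdgeTerm

    @property
    def children(self) -> tuple:
        return ()


@dataclass(frozen=True)
class Not:
    child: "Expression"

    @property
    def children(self) -> tuple:
        return (self.child,)


@dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires >= 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires >= 2 children")


Expression = Union[Leaf, Not, And, Or]


def iter_terms(expression: Expression) -> Iterator[EdgeTerm]:
    """Yield every leaf term of *expression* in left-to-right order."""
    if isinstance(expression, Leaf):
        yield expression.term
    else:
        for child in expression.children:
            yield from iter_terms(child)


def _check_negation_parity(expression: Expression, parity: bool = False) -> None:
    if isinstance(expression, Leaf):
        if expression.term.negated != parity:
            raise ValueError(
                f"term {expression.term.source!r}: negated flag "
                f"{expression.term.negated} does not match its NOT context"
            )
    elif isinstance(expression, Not):
        _check_negation_parity(expression.child, not parity)
    else:
        for child in expression.children:
            _check_negation_parity(child, parity)


@dataclass(frozen=True)
class TransferRule:
    """The gated Boolean expression determining one node's next state."""

    target: str
    expression: Expression

    def __post_init__(self) -> None:
        terms = list(iter_terms(self.expression))
        if not terms:
            raise ValueError(f"rule for {self.target!r} has no input terms")
        sources = [t.source for t in terms]
        dupes = {s for s in sources if sources.count(s) > 1}
        if dupes:
            raise ValueError(
                f"rule for {self.target!r}: duplicate edge(s) from "
                f"{sorted(dupes)} — one term per (target, source) pair"
            )
        _check_negation_parity(self.expression)

    @property
    def terms(self) -> list[EdgeTerm]:
        return list(iter_terms(self.expression))

    @property
    def sources(self) -> list[str]:
        return [t.source for t in self.terms]

    def text(self) -> str:
        return format_expression(self.expression)


# ---------------------------------------------------------------------------
# printing
# ---------------------------------------------------------------------------

def _format(expression: Expression, parent: str) -> str:
    if isinstance(expression, Leaf):
        t = expression.term
        coef = "" if t.r == 1 else f"{t.r}*"
        return f"{coef}{t.source}(t-{t.theta})"
    if isinstance(expression, Not):
        inner = _format(expression.child, "NOT")
        if isinstance(expression.child, (And, Or)):
            inner = f"({inner})"
        return f"NOT {inner}"
    if isinstance(expression, And):
        parts = []
        for child in expression.children:
            s = _format(child, "AND")
            if isinstance(child, Or):
                s = f"({s})"
            parts.append(s)
        return " AND ".join(parts)
    parts = [_format(child, "OR") for child in expression.children]
    return " OR ".join(parts)


def format_expression(expression: Expression) -> str:
    """Render an expression back into the rule grammar (inverse of parsing)."""
    return _format(expression, "")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<AND>\bAND\b)|(?P<OR>\bOR\b)|(?P<NOT>\bNOT\b)"
    r"|(?P<NAME>[A-Za-z_][A-Za-z0-9_/]*)"
    r"|(?P<INT>\d+)|(?P<MINUS>-)|(?P<STAR>\*)"
    r"|(?P<LPAREN>\()|(?P<RPAREN>\)))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].lstrip()
            if not rest:
                break
            raise RuleParseError(
                f"unexpected character {rest[0]!r} at position {pos}"
            )
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str, target: str):
        self.text = text
        self.target = target
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self, expect: str | None = None) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleParseError(
                f"rule for {self.target!r}: unexpected end of input "
                f"(expected {expect or 'more tokens'})"
            )
        if expect is not None and tok[0] != expect:
            raise RuleParseError(
                f"rule for {self.target!r}: expected {expect} but found "
                f"{tok[1]!r} at position {tok[2]}"
            )
        self.i += 1
        return tok

    # grammar: or_expr := and_expr (OR and_expr)*  — the parity argument
    # tracks how many enclosing NOTs apply, so leaf negated flags match
    # their NOT context.
    def parse(self) -> Expression:
        expr = self.or_expr(False)
        tok = self.peek()
        if tok is not None:
            raise RuleParseError(
                f"rule for {self.target!r}: unexpected token {tok[1]!r} "
                f"at position {tok[2]}"
            )
        return expr

    def or_expr(self, negated: bool) -> Expression:
        children = [self.and_expr(negated)]
        while self.peek() is not None and self.peek()[0] == "OR":
            self.next("OR")
            children.append(self.and_expr(negated))
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self, negated: bool) -> Expression:
        children = [self.unary(negated)]
        while self.peek() is not None and self.peek()[0] == "AND":
            self.next("AND")
            children.append(self.unary(negated))
        return children[0] if len(children) == 1 else And(tuple(children))

    def unary(self, negated: bool) -> Expression:
        tok = self.peek()
        if tok is None:
            raise RuleParseError(
                f"rule for {self.target!r}: unexpected end of input"
            )
        if tok[0] == "NOT":
            self.next("NOT")
            return Not(self.unary(not negated))
        if tok[0] == "LPAREN":
            self.next("LPAREN")
            expr = self.or_expr(negated)
            self.next("RPAREN")
            return expr
        return self.term(negated)

    def term(self, negated: bool) -> Expression:
        r = 1
        tok = self.peek()
        if tok is None:
            raise RuleParseError(
                f"rule for {self.target!r}: unexpected end of input"
            )
        if tok[0] in ("MINUS", "INT"):
            sign = 1
            if tok[0] == "MINUS":
                self.next("MINUS")
                sign = -1
            val = self.next("INT")
            r = sign * int(val[1])
            if r == 0:
                raise RuleParseError(
                    f"rule for {self.target!r}: coefficient r=0 at position "
                    f"{val[2]} (r must be nonzero)"
                )
            self.next("STAR")
        name = self.next("NAME")
        lp = self.next("LPAREN")
        tvar = self.next("NAME")
        if tvar[1] != "t":
            raise RuleParseError(
                f"rule for {self.target!r}: expected time variable 't' but "
                f"found {tvar[1]!r} at position {tvar[2]}"
            )
        self.next("MINUS")
        lag_tok = self.next("INT")
        lag = int(lag_tok[1])
        if lag <= 0:
            raise RuleParseError(
                f"rule for {self.target!r}: lag {lag} at position "
                f"{lag_tok[2]} must be >= 1"
            )
        self.next("RPAREN")
        return Leaf(EdgeTerm(source=name[1], theta=lag, r=r, negated=negated))


def parse_rule(text: str, target: str) -> TransferRule:
    """Parse a rule string in the ``r*NAME(t-theta)`` grammar.

    The integer coefficient before ``*`` is stored as the sustain/delay
    parameter ``r`` (absent coefficient means ``r = 1``); the lag inside
    ``(t-...)`` is the activation delay ``theta``.  NOT binds tighter than
    AND, which binds tighter than OR.

    Raises :class:`RuleParseError` naming the offending token on a lag <= 0,
    a zero coefficient, an unknown operator or unbalanced parentheses.
    """
    parser = _Parser(text, target)
    try:
        expression = parser.parse()
    except RuleParseError:
        raise
    except ValueError as exc:  # EdgeTerm validation
        raise RuleParseError(f"rule for {target!r}: {exc}") from exc
    return TransferRule(target=target, expression=expression)
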