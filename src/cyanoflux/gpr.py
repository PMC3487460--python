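"""Gene-protein-reaction (GPR) Boolean rules.

A GPR is a Boolean expression over gene locus tags that states which gene
products a reaction needs in order to carry flux: ``and`` joins subunits of a
complex (all required), ``or`` joins isozymes (any suffices).  A distinguished
``unknown`` leaf stands for an unidentified complementing gene product; it is
always satisfied and can never be knocked out, so a rule like
``psbO or unknown`` renders the reaction immune to the loss of *psbO*.

The concrete grammar accepted by :func:`parse_gpr`::

    expr   := term ( OR term )*
    term   := factor ( AND factor )*
    factor := GENE | UNKNOWN | "(" expr ")"

``and`` binds tighter than ``or`` (the usual COBRA convention).  Keywords are
case-insensitive; gene identifiers are compared case-sensitively after
whitespace trimming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Set, Tuple, Union


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    id: str

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True)
class Unknown:
    """Always-satisfiable placeholder for an unidentified complementing gene."""

    def __str__(self) -> str:
        return "unknown"


@dataclass(frozen=True)
class And:
    children: Tuple["GPRExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires at least 2 children")

    def __str__(self) -> str:
        return " and ".join(_child_str(c, wrap_or=True) for c in self.children)


@dataclass(frozen=True)
class Or:
    children: Tuple["GPRExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires at least 2 children")

    def __str__(self) -> str:
        return " or ".join(str(c) for c in self.children)


GPRExpression = Union[Gene, Unknown, And, Or]

UNKNOWN_TOKENS = frozenset({"unknown", "unknown_gene", "unknown gene"})

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _child_str(child: GPRExpression, wrap_or: bool) -> str:
    # ORs nested under an AND need parentheses to survive re-parsing.
    if wrap_or and isinstance(child, Or):
        return f"({child})"
    return str(child)


def _tokenize(text: str):
    tokens = []  # (token, position)
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str | None) -> GPRExpression | None:
    """Parse a GPR string into an expression tree.

    Empty or whitespace-only text yields ``None``: the reaction is spontaneous
    or not gene-associated and is never disabled by knockouts.

    Raises
    ------
    GPRSyntaxError
        On unbalanced parentheses or a dangling operator, with the character
        position of the problem.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    tokens = _tokenize(text)
    expr, idx = _parse_or(tokens, 0, text)
    if idx != len(tokens):
        raise GPRSyntaxError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return expr


def _parse_or(tokens, idx, text):
    children = []
    child, idx = _parse_and(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and tokens[idx][0].lower() == "or":
        idx += 1
        child, idx = _parse_and(tokens, idx, text)
        children.append(child)
    return _flatten(Or, children), idx


def _parse_and(tokens, idx, text):
    children = []
    child, idx = _parse_factor(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and tokens[idx][0].lower() == "and":
        idx += 1
        child, idx = _parse_factor(tokens, idx, text)
        children.append(child)
    return _flatten(And, children), idx


def _parse_factor(tokens, idx, text):
    if idx >= len(tokens):
        raise GPRSyntaxError("dangling operator or empty expression", len(text))
    tok, pos = tokens[idx]
    if tok == "(":
        expr, idx = _parse_or(tokens, idx + 1, text)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GPRSyntaxError("unbalanced parentheses: missing ')'", pos)
        return expr, idx + 1
    if tok == ")":
        raise GPRSyntaxError("unbalanced parentheses: unexpected ')'", pos)
    if tok.lower() in ("and", "or"):
        raise GPRSyntaxError(f"dangling operator {tok!r}", pos)
    if tok.lower() in UNKNOWN_TOKENS:
        return Unknown(), idx + 1
    return Gene(tok.strip()), idx + 1


def _flatten(cls, children):
    """Collapse nested same-type nodes: AND(AND(a,b),c) -> AND(a,b,c)."""
    flat = []
    for child in children:
        if isinstance(child, cls):
            flat.extend(child.children)
        else:
            flat.append(child)
    if len(flat) == 1:
        return flat[0]
    return cls(tuple(flat))


def is_active(expr: GPRExpression | None, knocked: Set[str]) -> bool:
    """Evaluate a GPR under a set of knocked-out genes.

    A missing rule (``None``) and the ``unknown`` leaf are always active; a
    gene leaf is active iff it is not knocked out.
    """
    if expr is None or isinstance(expr, Unknown):
        return True
    if isinstance(expr, Gene):
        return expr.id not in knocked
    if isinstance(expr, And):
        return all(is_active(c, knocked) for c in expr.children)
    if isinstance(expr, Or):
        return any(is_active(c, knocked) for c in expr.children)
    raise TypeError(f"not a GPR node: {expr!r}")


def genes_of(expr: GPRExpression | None) -> Set[str]:
    """All gene ids appearing in the expression (the ``unknown`` leaf excluded)."""
    if expr is None or isinstance(expr, Unknown):
        return set()
    if isinstance(expr, Gene):
        return {expr.id}
    out: Set[str] = set()
    for child in expr.children:
        out |= genes_of(child)
    return out


def reactions_disabled_by(model, knocked: Iterable[str]) -> Set[str]:
    """Ids of the reactions whose GPR evaluates false under the knockout set.

    Gene ids not present in the model are tolerated (they simply disable
    nothing); reactions without a GPR are never disabled.
    """
    knocked = set(knocked)
    disabled = set()
    for rxn in model.reactions:
        if rxn.gpr is not None and not is_active(rxn.gpr, knocked):
            disabled.add(rxn.id)
    return disabled
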