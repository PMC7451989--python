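"""Gene-protein-reaction (GPR) boolean expressions.

A GPR links a reaction to the genes whose products catalyse it. AND nodes
represent enzyme complexes (all subunits required); OR nodes represent
isozymes (any one suffices). An empty GPR means the reaction has no known
gene and is unaffected by gene deletions.

Grammar: parenthesised infix expressions with case-insensitive ``and`` /
``or``; AND binds tighter than OR, so ``a or b and c`` parses as
``a or (b and c)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Tuple, Union

# A node is a gene id (str) or an ("and"|"or", (children...)) pair.
Node = Union[str, Tuple[str, Tuple["Node", ...]]]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPR:
    """Boolean gene-association tree; ``root is None`` means no GPR."""

    root: Optional[Node] = None

    @classmethod
    def parse(cls, text: Optional[str]) -> "GPR":
        if text is None or not text.strip():
            return cls(None)
        tokens = _TOKEN_RE.findall(text)
        root, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GPRParseError(
                f"trailing tokens in GPR {text!r}: {tokens[pos:]}"
            )
        return cls(root)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> FrozenSet[str]:
        """All gene ids occurring as leaves."""
        return frozenset(_leaves(self.root)) if self.root is not None else frozenset()

    def evaluate(self, deleted: FrozenSet[str] | set) -> bool:
        """Is the reaction still catalysed after deleting ``deleted`` genes?

        An empty GPR always evaluates active: a reaction without a gene
        association cannot be removed by any deletion.
        """
        if self.root is None:
            return True
        return _eval(self.root, set(deleted))

    def is_isozyme(self) -> bool:
        """True when the top level of the tree is an OR (isozymes present)."""
        return isinstance(self.root, tuple) and self.root[0] == "or"

    def to_string(self) -> str:
        return _fmt(self.root, top=True) if self.root is not None else ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _parse_or(tokens, pos):
    left, pos = _parse_and(tokens, pos)
    children = [left]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return left, pos
    return ("or", _flatten("or", children)), pos


def _parse_and(tokens, pos):
    left, pos = _parse_atom(tokens, pos)
    children = [left]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return left, pos
    return ("and", _flatten("and", children)), pos


def _parse_atom(tokens, pos):
    if pos >= len(tokens):
        raise GPRParseError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GPRParseError("unbalanced parentheses in GPR")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRParseError(f"unexpected token {tok!r} in GPR")
    return tok, pos + 1


def _flatten(op, children):
    out = []
    for c in children:
        if isinstance(c, tuple) and c[0] == op:
            out.extend(c[1])
        else:
            out.append(c)
    return tuple(out)


def _leaves(node):
    if isinstance(node, str):
        yield node
    else:
        for c in node[1]:
            yield from _leaves(c)


def _eval(node, deleted):
    if isinstance(node, str):
        return node not in deleted
    op, children = node
    if op == "and":
        return all(_eval(c, deleted) for c in children)
    return any(_eval(c, deleted) for c in children)


def _fmt(node, top=False):
    if isinstance(node, str):
        return node
    op, children = node
    inner = f" {op} ".join(
        _fmt(c) if isinstance(c, str) else f"({_fmt(c)})" for c in children
    )
    return inner if top else inner
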