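"""Boolean gene-reaction association (GPR) rules.

A GPR rule links a reaction to the genes encoding its catalysts: ``AND``
for protein complexes that require every subunit, ``OR`` for functional
isoforms where any one gene product suffices.  An empty rule means the
reaction has no gene association and is always available when expression
data is mapped onto the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "GprTree",
    "GprLeaf",
    "GprNode",
    "GPR_EMPTY",
    "GprParseError",
    "parse_gpr",
    "render_gpr",
]


class GprTree:
    """Base class for GPR rule trees."""

    def evaluate(self, calls: Mapping[str, bool], default: bool = True) -> bool:
        """Evaluate the rule under a present/absent call map.

        ``calls`` maps gene id to ``True`` (present) / ``False`` (absent).
        Genes missing from the map take ``default`` (present by default:
        only explicit evidence of absence disables a reaction).
        """
        raise NotImplementedError

    def leaves(self) -> Iterator[str]:
        """Yield the gene ids appearing in the rule."""
        raise NotImplementedError

    @property
    def is_empty(self) -> bool:
        return isinstance(self, _GprEmpty)

    def genes(self) -> set[str]:
        return set(self.leaves())

    def __str__(self) -> str:
        return render_gpr(self)


@dataclass(frozen=True)
class _GprEmpty(GprTree):
    """No gene association: active under any call map."""

    def evaluate(self, calls, default=True):
        return True

    def leaves(self):
        return iter(())

    def __repr__(self):
        return "GPR_EMPTY"


GPR_EMPTY = _GprEmpty()


@dataclass(frozen=True)
class GprLeaf(GprTree):
    gene: str

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene leaf must be a nonempty id")

    def evaluate(self, calls, default=True):
        return bool(calls.get(self.gene, default))

    def leaves(self):
        yield self.gene


@dataclass(frozen=True)
class GprNode(GprTree):
    op: str  # "and" | "or"
    children: tuple[GprTree, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("operator node requires >=2 children")

    def evaluate(self, calls, default=True):
        results = (c.evaluate(calls, default) for c in self.children)
        return all(results) if self.op == "and" else any(results)

    def leaves(self):
        for child in self.children:
            yield from child.leaves()


class GprParseError(ValueError):
    """Raised for malformed rule strings; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_gpr(text: str) -> GprTree:
    """Parse a rule string into a :class:`GprTree`.

    Grammar: gene ids, case-insensitive ``and`` / ``or``, parentheses.
    A flat run of one operator needs no parentheses; mixing ``and`` and
    ``or`` at the same level is rejected (parenthesize to disambiguate).
    Empty or blank text yields the EMPTY rule.
    """
    if text is None or not text.strip():
        return GPR_EMPTY
    tokens = _tokenize(text)
    pos = 0

    def is_op(tok: str) -> bool:
        return tok.lower() in ("and", "or")

    def parse_expr() -> GprTree:
        nonlocal pos
        terms = [parse_term()]
        op: str | None = None
        while pos < len(tokens) and is_op(tokens[pos][0]):
            tok, at = tokens[pos]
            this_op = tok.lower()
            if op is None:
                op = this_op
            elif op != this_op:
                raise GprParseError(
                    f"mixed '{op}'/'{this_op}' without parentheses", at
                )
            pos += 1
            terms.append(parse_term())
        if op is None:
            return terms[0]
        return GprNode(op, tuple(terms))

    def parse_term() -> GprTree:
        nonlocal pos
        if pos >= len(tokens):
            at = tokens[-1][1] if tokens else 0
            raise GprParseError("dangling operator or empty term", at)
        tok, at = tokens[pos]
        if tok == "(":
            pos += 1
            inner = parse_expr()
            if pos >= len(tokens) or tokens[pos][0] != ")":
                raise GprParseError("unbalanced parentheses", at)
            pos += 1
            return inner
        if tok == ")":
            raise GprParseError("unexpected ')'", at)
        if is_op(tok):
            raise GprParseError(f"dangling operator {tok!r}", at)
        pos += 1
        return GprLeaf(tok)

    tree = parse_expr()
    if pos < len(tokens):
        raise GprParseError(f"unexpected token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def render_gpr(tree: GprTree) -> str:
    """Serialize a tree back to rule text; round-trips through parse_gpr."""
    if isinstance(tree, _GprEmpty):
        return ""
    if isinstance(tree, GprLeaf):
        return tree.gene
    assert isinstance(tree, GprNode)
    parts = []
    for child in tree.children:
        text = render_gpr(child)
        if isinstance(child, GprNode):
            text = f"({text})"
        parts.append(text)
    return f" {tree.op} ".join(parts)
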