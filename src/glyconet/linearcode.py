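"""LinearCode reader/writer and the extended pattern dialect of enzyme rules.

Structures
----------
Plain LinearCode, e.g. ``Ma3(Ma6)Mb4GNb4GN``.  The string reads from the
non-reducing termini (left) towards the reducing end (right): the rightmost
residue is the root, a residue's in-line predecessor and any parenthesised
groups immediately before it are its branches.

Patterns
--------
Enzyme substrate/product cells use an extended dialect:

* a leading ``(`` marks a *non-reducing-terminal anchor*: the leftmost
  explicit residue of the pattern must match a leaf of the subject glycan;
* ``*`` matches exactly one residue of any symbol (an optional anomer or
  position narrows it, e.g. ``*2``);
* ``...`` (or the ellipsis character) stands for any descending chain of
  zero or more residues with unconstrained linkages.

Patterns are fragments: they may be matched rooted at any residue of a
subject glycan, and subject residues may carry branches the pattern does not
mention (subtree embedding, not exact equality).

Constraints
-----------
Boolean expressions over pattern tests, with ``~`` (not), ``&`` (and) and
``or``; ``~`` binds tightest, then ``&``.  Atoms:

* ``Gnbis``      -- a bisecting GlcNAc (GN beta1-4 on the core beta-mannose)
                    is present;
* ``Ab``         -- any beta-galactose is present;
* ``X |Y``       -- pattern ``X`` matches inside the subtree rooted at some
                    residue matching ``Y``;
* ``_X |Y``      -- the *action site* lies inside the subtree rooted at a
                    residue matching ``X`` whose parent matches ``Y``;
* ``_P``         -- the action site and its ancestors match the linear path
                    pattern ``P`` (leftmost residue of ``P`` = the site);
* any other text -- a pattern that must match somewhere on the glycan.

The TeX-style ``$\\thicksim$`` rendering of the negation sign is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .glycan import (
    ANOMERS,
    Glycan,
    GlycanError,
    POSITIONS,
    Residue,
    SYMBOLS,
    UnknownSymbolError,
)


class LinearCodeError(GlycanError):
    """Syntax error in a LinearCode string; carries the character offset."""

    def __init__(self, message: str, offset: int = -1):
        super().__init__(f"{message} (offset {offset})" if offset >= 0 else message)
        self.offset = offset


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(?P<res>NN|GN|AN|M|A|F)(?P<an>[ab])?(?P<pos>[2346])?"
    r"|(?P<star>\*)(?P<san>[ab])?(?P<spos>[2346])?"
    r"|(?P<ell>\.\.\.|…)"
    r"|(?P<open>\()"
    r"|(?P<close>\))"
    r"|(?P<ws>\s+)"
)

RES, STAR, ELLIPSIS, OPEN, CLOSE = "res", "star", "ellipsis", "(", ")"


@dataclass
class _Token:
    kind: str
    offset: int
    symbol: Optional[str] = None
    anomer: Optional[str] = None
    pos: Optional[int] = None


def _tokenize(text: str, allow_wildcards: bool) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise LinearCodeError(f"unexpected character {text[i]!r}", i)
        if m.lastgroup != "ws":
            if m.group("res"):
                tokens.append(
                    _Token(
                        RES,
                        i,
                        symbol=m.group("res"),
                        anomer=m.group("an"),
                        pos=int(m.group("pos")) if m.group("pos") else None,
                    )
                )
            elif m.group("star"):
                if not allow_wildcards:
                    raise LinearCodeError("wildcard '*' not allowed in structures", i)
                tokens.append(
                    _Token(
                        STAR,
                        i,
                        anomer=m.group("san"),
                        pos=int(m.group("spos")) if m.group("spos") else None,
                    )
                )
            elif m.group("ell"):
                if not allow_wildcards:
                    raise LinearCodeError("'...' not allowed in structures", i)
                tokens.append(_Token(ELLIPSIS, i))
            elif m.group("open"):
                tokens.append(_Token(OPEN, i))
            else:
                tokens.append(_Token(CLOSE, i))
        i = m.end()
    return tokens


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def parse_structure(text: str) -> Glycan:
    """Parse plain LinearCode into a :class:`Glycan`.

    The rightmost residue is the reducing-end root and must carry no linkage;
    every other residue must carry both anomer and position.
    """
    tokens = _tokenize(text, allow_wildcards=False)
    if not tokens:
        raise LinearCodeError("empty glycan string", 0)
    glycan = _parse_chain(tokens, text)
    root = glycan.residue
    if root.anomer is not None or root.pos is not None:
        raise LinearCodeError(
            f"reducing-end residue {root.token!r} must not carry a linkage",
            tokens[-1].offset,
        )
    return glycan


def _parse_chain(tokens: list[_Token], text: str) -> Glycan:
    """Parse one chain: ``<child-chain> (branch)* <residue>``, rightmost = root."""
    last = tokens[-1]
    if last.kind != RES:
        raise LinearCodeError("expected a residue", last.offset)
    rest = tokens[:-1]
    children: list[Glycan] = []
    while rest and rest[-1].kind == CLOSE:
        depth = 0
        for i in range(len(rest) - 1, -1, -1):
            if rest[i].kind == CLOSE:
                depth += 1
            elif rest[i].kind == OPEN:
                depth -= 1
                if depth == 0:
                    break
        else:
            raise LinearCodeError("unbalanced ')'", rest[-1].offset)
        inner = rest[i + 1 : -1]
        if not inner:
            raise LinearCodeError("empty branch '()'", rest[i].offset)
        children.append(_parse_chain(inner, text))
        rest = rest[:i]
    if rest:
        children.append(_parse_chain(rest, text))
    residue = Residue(last.symbol, last.anomer, last.pos)
    for child in children:
        if child.residue.anomer is None or child.residue.pos is None:
            raise LinearCodeError(
                f"residue {child.residue.token!r} needs an anomer and a position",
                last.offset,
            )
    return Glycan(residue, tuple(reversed(children)))


def write_structure(glycan: Glycan) -> str:
    """Canonical LinearCode text; ``parse(write(g))`` is isomorphic to ``g``."""
    return glycan.canonical


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class PatternNode:
    """One node of a pattern tree.

    ``kind`` is ``res`` (symbol set), ``star`` (any single residue) or
    ``ellipsis`` (any chain, only meaningful as a leaf, where it is vacuous
    and kept for round-tripping the printed rules).  ``anchored`` marks the
    non-reducing-terminal anchor.
    """

    kind: str
    symbol: Optional[str] = None
    anomer: Optional[str] = None
    pos: Optional[int] = None
    children: tuple["PatternNode", ...] = ()
    anchored: bool = False
    offset: int = -1  # position of the source token, for error messages

    @property
    def token(self) -> str:
        if self.kind == ELLIPSIS:
            return "..."
        base = "*" if self.kind == STAR else self.symbol
        return f"{base}{self.anomer or ''}{self.pos if self.pos is not None else ''}"

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def __str__(self) -> str:
        if not self.children:
            body = self.token
        else:
            parts = [str(self.children[0])]
            parts.extend(f"({c})" for c in self.children[1:])
            parts.append(self.token)
            body = "".join(parts)
        return body


def parse_pattern(text: str) -> PatternNode:
    """Parse a pattern cell into a :class:`PatternNode` tree.

    A single unmatched leading ``(`` is the terminal anchor and marks the
    leftmost explicit node of the pattern.
    """
    text = text.strip()
    anchored = False
    tokens = _tokenize(text, allow_wildcards=True)
    if tokens and tokens[0].kind == OPEN:
        opens = sum(1 for t in tokens if t.kind == OPEN)
        closes = sum(1 for t in tokens if t.kind == CLOSE)
        if opens == closes + 1:
            anchored = True
            tokens = tokens[1:]
    if not tokens:
        raise LinearCodeError("empty pattern", 0)
    root = _parse_pattern_chain(tokens)
    if anchored:
        # the anchor is the leftmost explicit node, which is always a leaf
        target = min(root.walk(), key=lambda n: n.offset)
        root = _mark_anchor(root, target)
    return root


def _parse_pattern_chain(tokens: list[_Token]) -> PatternNode:
    last = tokens[-1]
    if last.kind not in (RES, STAR, ELLIPSIS):
        raise LinearCodeError("expected a residue, '*' or '...'", last.offset)
    rest = tokens[:-1]
    children: list[PatternNode] = []
    while rest and rest[-1].kind == CLOSE:
        depth = 0
        for i in range(len(rest) - 1, -1, -1):
            if rest[i].kind == CLOSE:
                depth += 1
            elif rest[i].kind == OPEN:
                depth -= 1
                if depth == 0:
                    break
        else:
            raise LinearCodeError("unbalanced ')'", rest[-1].offset)
        inner = rest[i + 1 : -1]
        if not inner:
            raise LinearCodeError("empty branch '()'", rest[i].offset)
        children.append(_parse_pattern_chain(inner))
        rest = rest[:i]
    if rest:
        children.append(_parse_pattern_chain(rest))
    children.reverse()
    return PatternNode(
        kind=ELLIPSIS if last.kind == ELLIPSIS else (STAR if last.kind == STAR else RES),
        symbol=last.symbol,
        anomer=last.anomer,
        pos=last.pos,
        children=tuple(children),
        offset=last.offset,
    )


def _mark_anchor(root: PatternNode, target: PatternNode) -> PatternNode:
    def rebuild(node: PatternNode) -> PatternNode:
        return PatternNode(
            node.kind,
            node.symbol,
            node.anomer,
            node.pos,
            tuple(rebuild(c) for c in node.children),
            anchored=node.anchored or node is target,
            offset=node.offset,
        )

    return rebuild(root)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


class ConstraintExpr:
    """Base class of constraint ASTs (see module docstring for the grammar)."""


@dataclass(frozen=True)
class TrueExpr(ConstraintExpr):
    def __str__(self) -> str:
        return ""


@dataclass(frozen=True)
class NotExpr(ConstraintExpr):
    operand: ConstraintExpr

    def __str__(self) -> str:
        return f"~{self.operand}"


@dataclass(frozen=True)
class AndExpr(ConstraintExpr):
    operands: tuple[ConstraintExpr, ...]

    def __str__(self) -> str:
        return " & ".join(str(o) for o in self.operands)


@dataclass(frozen=True)
class OrExpr(ConstraintExpr):
    operands: tuple[ConstraintExpr, ...]

    def __str__(self) -> str:
        return " or ".join(str(o) for o in self.operands)


@dataclass(frozen=True, eq=False)
class PatternAtom(ConstraintExpr):
    """The pattern matches somewhere on the glycan."""

    pattern: PatternNode
    text: str

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True, eq=False)
class BranchAtom(ConstraintExpr):
    """``X |Y``: pattern X matches within the subtree rooted at a Y residue."""

    inner: PatternNode
    branch: PatternNode
    text: str

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True, eq=False)
class TargetBranchAtom(ConstraintExpr):
    """``_X |Y``: the action site is inside a branch X whose parent matches Y."""

    branch: PatternNode
    parent: PatternNode
    text: str

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True, eq=False)
class TargetPathAtom(ConstraintExpr):
    """``_P``: the site and its ancestors match the linear path pattern P."""

    path: PatternNode
    text: str

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class NamedAtom(ConstraintExpr):
    """``Gnbis`` (bisecting GlcNAc present) or ``Ab`` (any beta-Gal present)."""

    name: str

    def __str__(self) -> str:
        return self.name


_NAMED_ATOMS = ("Gnbis", "Ab")


class UnknownAtomError(GlycanError):
    pass


def parse_constraint(text: str) -> ConstraintExpr:
    """Parse a constraint cell; an empty cell is the always-true expression."""
    text = text.replace("$\\thicksim$", "~").replace("∼", "~").strip()
    if not text:
        return TrueExpr()
    or_parts = re.split(r"\s+or\s+", text)
    ors = []
    for part in or_parts:
        and_parts = [p.strip() for p in part.split("&")]
        ands = [_parse_atom(p) for p in and_parts if p]
        if not ands:
            raise UnknownAtomError(f"empty conjunct in constraint {text!r}")
        ors.append(ands[0] if len(ands) == 1 else AndExpr(tuple(ands)))
    return ors[0] if len(ors) == 1 else OrExpr(tuple(ors))


def _parse_atom(text: str) -> ConstraintExpr:
    if text.startswith("~"):
        return NotExpr(_parse_atom(text[1:].strip()))
    if text in _NAMED_ATOMS:
        return NamedAtom(text)
    if text.startswith("_"):
        body = text[1:].strip()
        if "|" in body:
            x, y = (s.strip() for s in body.split("|", 1))
            return TargetBranchAtom(parse_pattern(x), parse_pattern(y), text)
        return TargetPathAtom(parse_pattern(body), text)
    if "|" in text:
        x, y = (s.strip() for s in text.split("|", 1))
        return BranchAtom(parse_pattern(x), parse_pattern(y), text)
    try:
        return PatternAtom(parse_pattern(text), text)
    except (LinearCodeError, UnknownSymbolError) as exc:
        raise UnknownAtomError(f"cannot parse constraint atom {text!r}: {exc}") from exc
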