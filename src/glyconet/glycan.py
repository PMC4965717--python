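"""Immutable rooted-tree model of N-glycans.

A glycan is modelled as a rooted tree of monosaccharide residues.  The root
is the reducing-end GlcNAc (the residue attached to asparagine in vivo; the
protein side is not modelled).  Every non-root residue carries the anomeric
configuration (``a``/``b``) and the carbon position (2, 3, 4 or 6) of its
linkage to the parent residue.  Sialic acid (``NN``) links from its own C2,
so ``NN a3`` denotes an alpha2-3 linkage; only the acceptor-side position is
stored.

Residue symbols follow LinearCode: ``M`` mannose, ``GN`` N-acetylglucosamine,
``A`` galactose, ``AN`` N-acetylgalactosamine, ``F`` fucose and ``NN``
N-acetylneuraminic (sialic) acid.

Two structural invariants are enforced at construction time: a parent may
carry at most one substituent per position, and children are stored in
canonical order (ascending position), which makes the rendered LinearCode
string of a tree a canonical key for isomorphism testing.

Addresses
---------
Residues are addressed by the path of ``(position, symbol)`` pairs from the
root, e.g. ``((4, "GN"), (4, "M"), (3, "M"))`` is the core alpha3-mannose.
Positions are unique among siblings, so an address names at most one residue.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional

SYMBOLS = ("M", "GN", "A", "AN", "F", "NN")
ANOMERS = ("a", "b")
POSITIONS = (2, 3, 4, 6)

#: address of a residue: path of (link position, symbol) pairs from the root
Address = tuple


class GlycanError(ValueError):
    """Base class for structural errors."""


class UnknownSymbolError(GlycanError):
    pass


class OccupiedPositionError(GlycanError):
    """Attachment position already carries a substituent."""


class AddressNotFoundError(GlycanError, KeyError):
    pass


class NonTerminalRemovalError(GlycanError):
    """Only leaf residues can be hydrolysed off."""


@dataclass(frozen=True, order=True)
class Residue:
    """One monosaccharide with its linkage to the parent.

    ``anomer``/``pos`` are ``None`` only for the reducing-end root.
    """

    symbol: str
    anomer: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.symbol not in SYMBOLS:
            raise UnknownSymbolError(f"unknown residue symbol {self.symbol!r}")
        if self.anomer is not None and self.anomer not in ANOMERS:
            raise GlycanError(f"invalid anomer {self.anomer!r}")
        if self.pos is not None and self.pos not in POSITIONS:
            raise GlycanError(f"invalid linkage position {self.pos!r}")

    @property
    def token(self) -> str:
        """LinearCode token, e.g. ``Ma3`` or ``GN`` for the root."""
        return f"{self.symbol}{self.anomer or ''}{self.pos if self.pos is not None else ''}"


@dataclass(frozen=True)
class Glycan:
    """A residue with its ordered branches; the whole tree is the glycan.

    Instances are immutable; ``attach``/``detach`` return new trees.
    Children are normalised to ascending linkage position on construction.
    """

    residue: Residue
    children: tuple["Glycan", ...] = ()
    # canonical LinearCode of the subtree, filled in __post_init__
    _canon: str = field(init=False, repr=False, compare=False, default="")

    def __post_init__(self) -> None:
        for child in self.children:
            if child.residue.anomer is None or child.residue.pos is None:
                raise GlycanError(
                    f"non-root residue {child.residue.token!r} must carry anomer and position"
                )
        positions = [c.residue.pos for c in self.children]
        if len(positions) != len(set(positions)):
            raise OccupiedPositionError(
                f"duplicate substituent position on {self.residue.token!r}: {sorted(positions)}"
            )
        ordered = tuple(sorted(self.children, key=lambda c: c.residue.pos))
        object.__setattr__(self, "children", ordered)
        object.__setattr__(self, "_canon", _render(self))

    # -- canonical form ------------------------------------------------

    @property
    def canonical(self) -> str:
        """Canonical LinearCode key: equal iff the trees are isomorphic."""
        return self._canon

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Glycan) and self._canon == other._canon

    def __hash__(self) -> int:
        return hash(self._canon)

    # -- traversal -----------------------------------------------------

    def walk(self) -> Iterator[tuple[Address, "Glycan"]]:
        """Yield ``(address, subtree)`` in pre-order over canonical child order."""
        stack = [((), self)]
        while stack:
            addr, node = stack.pop()
            yield addr, node
            for child in reversed(node.children):
                stack.append((addr + ((child.residue.pos, child.residue.symbol),), child))

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __len__(self) -> int:
        return 1 + sum(len(c) for c in self.children)

    def node_at(self, address: Address) -> "Glycan":
        node = self
        for pos, symbol in address:
            for child in node.children:
                if child.residue.pos == pos and child.residue.symbol == symbol:
                    node = child
                    break
            else:
                raise AddressNotFoundError(f"no residue at address {address!r}")
        return node

    def child_at(self, pos: int) -> Optional["Glycan"]:
        for child in self.children:
            if child.residue.pos == pos:
                return child
        return None

    def composition(self) -> Counter:
        """Residue counts per monosaccharide symbol."""
        counts: Counter = Counter()
        for _, node in self.walk():
            counts[node.residue.symbol] += 1
        return counts

    # -- structural editing --------------------------------------------

    def attach(self, address: Address, new: Residue) -> "Glycan":
        """Return a new glycan with ``new`` attached under the residue at ``address``.

        Raises :class:`OccupiedPositionError` if the position is taken and
        :class:`AddressNotFoundError` if the address does not exist.
        """
        if new.anomer is None or new.pos is None:
            raise GlycanError("attached residue must carry anomer and position")

        def rebuild(node: Glycan, path: Address) -> Glycan:
            if not path:
                if node.child_at(new.pos) is not None:
                    raise OccupiedPositionError(
                        f"position {new.pos} on {node.residue.token!r} is occupied"
                    )
                return Glycan(node.residue, node.children + (Glycan(new),))
            (pos, symbol), rest = path[0], path[1:]
            new_children = []
            hit = False
            for child in node.children:
                if not hit and child.residue.pos == pos and child.residue.symbol == symbol:
                    new_children.append(rebuild(child, rest))
                    hit = True
                else:
                    new_children.append(child)
            if not hit:
                raise AddressNotFoundError(f"no residue at address {address!r}")
            return Glycan(node.residue, tuple(new_children))

        return rebuild(self, address)

    def detach(self, address: Address) -> "Glycan":
        """Return a new glycan with the terminal residue at ``address`` removed."""
        if not address:
            raise NonTerminalRemovalError("cannot detach the root residue")

        def rebuild(node: Glycan, path: Address) -> Glycan:
            (pos, symbol), rest = path[0], path[1:]
            new_children = []
            hit = False
            for child in node.children:
                if not hit and child.residue.pos == pos and child.residue.symbol == symbol:
                    hit = True
                    if rest:
                        new_children.append(rebuild(child, rest))
                    else:
                        if not child.is_leaf:
                            raise NonTerminalRemovalError(
                                f"residue at {address!r} is not terminal"
                            )
                        continue
                else:
                    new_children.append(child)
            if not hit:
                raise AddressNotFoundError(f"no residue at address {address!r}")
            return Glycan(node.residue, tuple(new_children))

        return rebuild(self, address)

    def find_residues(
        self,
        symbol: Optional[str] = None,
        anomer: Optional[str] = None,
        pos: Optional[int] = None,
        terminal_only: bool = False,
    ) -> list[Address]:
        """Addresses of residues matching the query, in canonical traversal order.

        ``None`` fields match anything.
        """
        out = []
        for addr, node in self.walk():
            r = node.residue
            if symbol is not None and r.symbol != symbol:
                continue
            if anomer is not None and r.anomer != anomer:
                continue
            if pos is not None and r.pos != pos:
                continue
            if terminal_only and not node.is_leaf:
                continue
            out.append(addr)
        return out

    def __str__(self) -> str:
        return self._canon

    def __repr__(self) -> str:
        return f"Glycan({self._canon!r})"


def _render(node: Glycan) -> str:
    """LinearCode text of a subtree, children in stored (canonical) order.

    The lowest-position child is written in line, the remaining branches are
    parenthesised, matching the conventional layout (alpha3 arm before alpha6).
    """
    if not node.children:
        return node.residue.token
    parts = [_render(node.children[0])]
    for child in node.children[1:]:
        parts.append(f"({_render(child)})")
    parts.append(node.residue.token)
    return "".join(parts)
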