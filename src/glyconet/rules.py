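"""Enzyme reaction rules: the bundled database and the substrate matcher.

Each rule describes one elementary glycosylation step: a transferase (``GT``)
adds one residue to an acceptor residue matched by the substrate pattern, a
hydrolase (``GH``) removes one terminal residue.  The residue transferred or
removed and the acceptor it attaches to are derived automatically by
aligning the substrate and product pattern trees, which must differ by
exactly one residue.

On top of the substrate pattern and the constraint expression, a rule may
carry values for the eight substrate-specificity predicates used in
systems-glycobiology enzyme models:

``substMinStruct``
    structure that must be contained in the substrate, aligned at the
    reducing end;
``substMaxStruct``
    structure that must contain the substrate (aligned at the reducing end);
``substNABranch``
    pattern that must not match anywhere on the substrate;
``substNAStruct``
    structure that must not be contained in the substrate at the root;
``substNAResidue``
    residue symbol that must be absent;
``targetBranch`` / ``targetNABranch``
    branch (a linear path written leaf-to-root, e.g. ``Ma3Mb4`` for the core
    alpha3 arm) that must / must not contain the action site;
``isTerminalTarget``
    the action site must be a leaf.

Blank predicate values are vacuously true.  A rule acts only where the
substrate pattern matches, the constraint holds and every defined predicate
is satisfied.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .glycan import Address, Glycan, GlycanError, Residue
from .linearcode import (
    AndExpr,
    BranchAtom,
    ConstraintExpr,
    NamedAtom,
    NotExpr,
    OrExpr,
    PatternAtom,
    PatternNode,
    TargetBranchAtom,
    TargetPathAtom,
    TrueExpr,
    parse_constraint,
    parse_pattern,
    parse_structure,
)

logger = logging.getLogger(__name__)

TRANSFERASE = "GT"
HYDROLASE = "GH"


class RuleError(GlycanError):
    """Malformed rule definition; carries the rule index where known."""


# ---------------------------------------------------------------------------
# pattern matching
# ---------------------------------------------------------------------------


def _label_ok(p: PatternNode, node: Glycan) -> bool:
    if p.kind == "res" and p.symbol != node.residue.symbol:
        return False
    if p.anomer is not None and node.residue.anomer != p.anomer:
        return False
    if p.pos is not None and node.residue.pos != p.pos:
        return False
    if p.anchored and p.kind != "ellipsis" and not node.is_leaf:
        return False
    return True


def match_at(p: PatternNode, node: Glycan, addr: Address = ()) -> list[dict]:
    """All embeddings of pattern ``p`` rooted at ``node``.

    Each embedding is returned as a binding ``{id(pattern node): address}``.
    Subject residues may carry branches the pattern does not mention;
    ellipsis nodes are vacuous (they stand for "any further chain").
    """
    if not _label_ok(p, node):
        return []
    pchildren = [c for c in p.children if c.kind != "ellipsis"]
    out = []
    for b in _match_children(pchildren, list(node.children), addr):
        b[id(p)] = addr
        out.append(b)
    return out


def _match_children(pcs: list, scs: list, addr: Address) -> list[dict]:
    if not pcs:
        return [{}]
    first, rest = pcs[0], pcs[1:]
    out = []
    for i, sc in enumerate(scs):
        caddr = addr + ((sc.residue.pos, sc.residue.symbol),)
        for b1 in match_at(first, sc, caddr):
            remaining = scs[:i] + scs[i + 1 :]
            for b2 in _match_children(rest, remaining, addr):
                out.append({**b1, **b2})
    return out


def match_anywhere(p: PatternNode, g: Glycan) -> list[tuple[Address, dict]]:
    """All embeddings of ``p`` rooted at any residue of ``g``, traversal order."""
    out = []
    for addr, node in g.walk():
        for b in match_at(p, node, addr):
            out.append((addr, b))
    return out


def contains(big: Glycan, small: Glycan) -> bool:
    """Rooted embedding test: ``small`` is a substructure of ``big``.

    Both trees are aligned at the reducing end; ``big`` may carry extra
    branches anywhere.
    """
    r_small, r_big = small.residue, big.residue
    if (r_small.symbol, r_small.anomer, r_small.pos) != (
        r_big.symbol,
        r_big.anomer,
        r_big.pos,
    ):
        return False
    for child in small.children:
        counterpart = big.child_at(child.residue.pos)
        if counterpart is None or not contains(counterpart, child):
            return False
    return True


def _chain_of(p: PatternNode) -> list[PatternNode]:
    """A linear pattern as a list leaf-first; errors on branched patterns."""
    chain = []
    node: Optional[PatternNode] = p
    while node is not None:
        chain.append(node)
        kids = [c for c in node.children if c.kind != "ellipsis"]
        if len(kids) > 1:
            raise RuleError(f"branch pattern {p} must be a linear path")
        node = kids[0] if kids else None
    chain.reverse()  # leaf first
    return chain


def _path_matches_up(g: Glycan, addr: Address, chain: list[PatternNode]) -> bool:
    """True if the residue at ``addr`` and its ancestors match ``chain`` (leaf-first)."""
    for i, pnode in enumerate(chain):
        depth = len(addr) - i
        if depth < 0:
            return False
        node = g.node_at(addr[:depth])
        if pnode.kind == "res" and pnode.symbol != node.residue.symbol:
            return False
        if pnode.anomer is not None and node.residue.anomer != pnode.anomer:
            return False
        if pnode.pos is not None and node.residue.pos != pnode.pos:
            return False
    return True


def branch_roots(g: Glycan, branch: PatternNode) -> list[Address]:
    """Addresses whose upward residue chain matches the branch path pattern.

    The pattern is written leaf-to-root (``Ma3Mb4`` = an alpha3-Man on a
    beta4-Man); the leftmost pattern residue is the branch root.
    """
    chain = _chain_of(branch)  # leaf-first = branch root, then its ancestors
    return [addr for addr, _ in g.walk() if _path_matches_up(g, addr, chain)]


# ---------------------------------------------------------------------------
# constraint evaluation
# ---------------------------------------------------------------------------

_GNBIS_PATTERN = parse_pattern("GNb4Mb4")


def eval_constraint(expr: ConstraintExpr, g: Glycan, site: Address) -> bool:
    if isinstance(expr, TrueExpr):
        return True
    if isinstance(expr, NotExpr):
        return not eval_constraint(expr.operand, g, site)
    if isinstance(expr, AndExpr):
        return all(eval_constraint(o, g, site) for o in expr.operands)
    if isinstance(expr, OrExpr):
        return any(eval_constraint(o, g, site) for o in expr.operands)
    if isinstance(expr, NamedAtom):
        if expr.name == "Gnbis":
            return bool(match_anywhere(_GNBIS_PATTERN, g))
        if expr.name == "Ab":
            return bool(g.find_residues(symbol="A", anomer="b"))
        raise RuleError(f"unknown named atom {expr.name!r}")
    if isinstance(expr, PatternAtom):
        return bool(match_anywhere(expr.pattern, g))
    if isinstance(expr, BranchAtom):
        for addr, _ in match_anywhere(expr.branch, g):
            if match_anywhere(expr.inner, g.node_at(addr)):
                return True
        return False
    if isinstance(expr, TargetBranchAtom):
        # branch roots: residues matching `branch` whose ancestors match `parent`
        chain = _chain_of(expr.branch) + _chain_of(expr.parent)
        for addr, _ in g.walk():
            if _path_matches_up(g, addr, chain) and site[: len(addr)] == addr:
                return True
        return False
    if isinstance(expr, TargetPathAtom):
        return _path_matches_up(g, site, _chain_of(expr.path))
    raise RuleError(f"unhandled constraint node {expr!r}")


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Specificity:
    """Optional values of the eight substrate-specificity predicates."""

    subst_min_struct: Optional[Glycan] = None
    subst_max_struct: Optional[Glycan] = None
    subst_na_branch: Optional[PatternNode] = None
    subst_na_struct: Optional[Glycan] = None
    subst_na_residue: Optional[str] = None
    target_branch: Optional[PatternNode] = None
    target_na_branch: Optional[PatternNode] = None
    is_terminal_target: bool = False


@dataclass(frozen=True, eq=False)
class EnzymeRule:
    """One row of the rule table (see module docstring)."""

    index: int
    enzyme: str
    ec: str
    kind: str
    substrate_pattern: PatternNode
    product_pattern: PatternNode
    constraint: ConstraintExpr
    specificity: Specificity = field(default_factory=Specificity)
    source_note: str = ""
    substrate_text: str = ""
    product_text: str = ""
    constraint_text: str = ""
    # derived by pattern alignment:
    action_residue: Residue = None  # type: ignore[assignment]
    target_node: PatternNode = None  # type: ignore[assignment]

    @property
    def resfuncgroup(self) -> str:
        """Symbol of the residue transferred (GT) or removed (GH)."""
        return self.action_residue.symbol

    @property
    def link_fg(self) -> str:
        """Linkage of the transferred residue, e.g. ``a6``."""
        return f"{self.action_residue.anomer}{self.action_residue.pos}"

    @property
    def res_att2fg(self) -> Optional[str]:
        """Residue class the functional group attaches to (GT only)."""
        return self.target_node.symbol if self.kind == TRANSFERASE else None

    @property
    def link_res_att2fg(self) -> Optional[str]:
        t = self.target_node
        if t.anomer is None and t.pos is None:
            return None
        return f"{t.anomer or ''}{t.pos if t.pos is not None else ''}"

    def __repr__(self) -> str:
        return f"EnzymeRule({self.index}: {self.enzyme} {self.substrate_text!r} -> {self.product_text!r})"


@dataclass(frozen=True)
class MatchSite:
    """One place a rule can act: the acceptor (GT) or leaving residue (GH)."""

    rule_index: int
    address: Address
    bindings: tuple = ()  # (pattern token, subject address) pairs for wildcards


# -- substrate/product alignment --------------------------------------------


def _pkey(p: PatternNode) -> str:
    """Order-insensitive structural key of a pattern subtree (anchors ignored)."""
    kids = sorted(_pkey(c) for c in p.children)
    return p.token + ("(" + ",".join(kids) + ")" if kids else "")


def _derive_action(rule_index: int, kind: str, sub: PatternNode, prod: PatternNode):
    """Align substrate and product patterns; find the one-residue difference.

    Returns ``(action residue, target node in the substrate pattern)`` where
    the target is the acceptor residue (GT) or the residue removed (GH).
    """
    if kind == TRANSFERASE:
        small, big = sub, prod
    else:
        small, big = prod, sub

    def align(s: PatternNode, b: PatternNode):
        if _pkey(PatternNode(s.kind, s.symbol, s.anomer, s.pos)) != _pkey(
            PatternNode(b.kind, b.symbol, b.anomer, b.pos)
        ):
            raise RuleError(f"rule {rule_index}: patterns do not align at {s.token}")
        s_kids = [c for c in s.children if c.kind != "ellipsis"]
        b_kids = [c for c in b.children if c.kind != "ellipsis"]
        s_left, b_left = list(s_kids), list(b_kids)
        for sk in list(s_left):
            for bk in list(b_left):
                if _pkey(sk) == _pkey(bk):
                    s_left.remove(sk)
                    b_left.remove(bk)
                    break
        if not s_left and len(b_left) == 1 and not b_left[0].children:
            return s, b_left[0]
        if len(s_left) == 1 and len(b_left) == 1:
            return align(s_left[0], b_left[0])
        raise RuleError(
            f"rule {rule_index}: substrate and product patterns must differ "
            f"by exactly one residue"
        )

    anchor_small, extra_big = align(small, big)
    if extra_big.kind != "res" or extra_big.anomer is None or extra_big.pos is None:
        raise RuleError(
            f"rule {rule_index}: transferred residue must be explicit with linkage"
        )
    residue = Residue(extra_big.symbol, extra_big.anomer, extra_big.pos)
    if kind == TRANSFERASE:
        # `small` is the substrate: the aligned node is the acceptor
        return residue, anchor_small
    # hydrolase: `big` is the substrate: the extra node is the one removed
    return residue, extra_big


# -- matching and specificity ------------------------------------------------


def match_sites(rule: EnzymeRule, g: Glycan) -> list[MatchSite]:
    """All distinct sites where the rule applies, in canonical traversal order.

    A site is the address of the acceptor residue (transferase) or of the
    residue to be removed (hydrolase).  Sites failing the constraint, any
    defined specificity predicate, position availability (GT) or terminality
    (GH) are dropped.
    """
    seen: set[Address] = set()
    sites: list[MatchSite] = []
    for addr, node in g.walk():
        for binding in match_at(rule.substrate_pattern, node, addr):
            t_addr = binding[id(rule.target_node)]
            if t_addr in seen:
                continue
            seen.add(t_addr)
            t_node = g.node_at(t_addr)
            if rule.kind == TRANSFERASE:
                if t_node.child_at(rule.action_residue.pos) is not None:
                    continue
            else:
                if not t_node.is_leaf:
                    continue
            wildcards = tuple(
                (p.token, binding[id(p)])
                for p in rule.substrate_pattern.walk()
                if p.kind == "star" and id(p) in binding
            )
            site = MatchSite(rule.index, t_addr, wildcards)
            if check_specificity(rule, g, site):
                sites.append(site)
    return sites


def check_specificity(rule: EnzymeRule, g: Glycan, site: MatchSite) -> bool:
    """Constraint plus the eight predicates; blank predicates are vacuous."""
    if not eval_constraint(rule.constraint, g, site.address):
        return False
    s = rule.specificity
    if s.subst_min_struct is not None and not contains(g, s.subst_min_struct):
        return False
    if s.subst_max_struct is not None and not contains(s.subst_max_struct, g):
        return False
    if s.subst_na_branch is not None and match_anywhere(s.subst_na_branch, g):
        return False
    if s.subst_na_struct is not None and contains(g, s.subst_na_struct):
        return False
    if s.subst_na_residue is not None and g.composition()[s.subst_na_residue] > 0:
        return False
    if s.target_branch is not None and not _site_in_branch(g, site.address, s.target_branch):
        return False
    if s.target_na_branch is not None and _site_in_branch(g, site.address, s.target_na_branch):
        return False
    if s.is_terminal_target and not g.node_at(site.address).is_leaf:
        return False
    return True


def _site_in_branch(g: Glycan, site: Address, branch: PatternNode) -> bool:
    return any(site[: len(a)] == a for a in branch_roots(g, branch))


# ---------------------------------------------------------------------------
# database loading
# ---------------------------------------------------------------------------

#: CSV columns of the bundled rule database
DB_COLUMNS = (
    "index",
    "enzyme",
    "ec",
    "kind",
    "substrate_pattern",
    "product_pattern",
    "constraint",
    "subst_min_struct",
    "subst_max_struct",
    "subst_na_branch",
    "subst_na_struct",
    "subst_na_residue",
    "target_branch",
    "target_na_branch",
    "is_terminal_target",
    "source_note",
)

_EC_RE_TEXT = r"^\d+\.\d+\.\d+\.\d+$"


def default_db_path():
    """Path-like handle on the bundled 27-rule database."""
    return resources.files("glyconet").joinpath("data/rules.csv")


def load_rule_db(path=None) -> list[EnzymeRule]:
    """Load and validate an enzyme-rule CSV; defaults to the bundled table."""
    handle = default_db_path() if path is None else path
    with open(str(handle), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
        missing = set(DB_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise RuleError(
            f"rule database {handle} is missing columns: {', '.join(sorted(missing))}"
        )
    if not rows:
        logger.warning("rule database %s is empty", handle)
        return []
    rules: list[EnzymeRule] = []
    seen_idx: set[int] = set()
    for n, row in enumerate(rows, start=2):
        try:
            idx = int(row["index"])
            if idx in seen_idx:
                raise RuleError(f"duplicate rule index {idx}")
            seen_idx.add(idx)
            kind = row["kind"].strip()
            if kind not in (TRANSFERASE, HYDROLASE):
                raise RuleError(f"unknown enzyme kind {kind!r}")
            ec = row["ec"].strip()
            if not re.match(_EC_RE_TEXT, ec):
                raise RuleError(f"invalid EC number {ec!r}")
            sub = parse_pattern(row["substrate_pattern"])
            prod = parse_pattern(row["product_pattern"])
            constraint = parse_constraint(row.get("constraint", "") or "")
            spec = Specificity(
                subst_min_struct=_opt_structure(row.get("subst_min_struct")),
                subst_max_struct=_opt_structure(row.get("subst_max_struct")),
                subst_na_branch=_opt_pattern(row.get("subst_na_branch")),
                subst_na_struct=_opt_structure(row.get("subst_na_struct")),
                subst_na_residue=(row.get("subst_na_residue") or "").strip() or None,
                target_branch=_opt_pattern(row.get("target_branch")),
                target_na_branch=_opt_pattern(row.get("target_na_branch")),
                is_terminal_target=(row.get("is_terminal_target") or "").strip().lower()
                in ("1", "true", "yes"),
            )
            residue, target = _derive_action(idx, kind, sub, prod)
            rules.append(
                EnzymeRule(
                    index=idx,
                    enzyme=row["enzyme"].strip(),
                    ec=ec,
                    kind=kind,
                    substrate_pattern=sub,
                    product_pattern=prod,
                    constraint=constraint,
                    specificity=spec,
                    source_note=(row.get("source_note") or "").strip(),
                    substrate_text=row["substrate_pattern"].strip(),
                    product_text=row["product_pattern"].strip(),
                    constraint_text=(row.get("constraint") or "").strip(),
                    action_residue=residue,
                    target_node=target,
                )
            )
        except (KeyError, ValueError) as exc:
            raise RuleError(f"rule database row {n}: {exc}") from exc
    return rules


def _opt_pattern(text: Optional[str]) -> Optional[PatternNode]:
    text = (text or "").strip()
    return parse_pattern(text) if text else None


def _opt_structure(text: Optional[str]) -> Optional[Glycan]:
    text = (text or "").strip()
    return parse_structure(text) if text else None


def select_rules(
    rules: Iterable[EnzymeRule], selector: str
) -> list[EnzymeRule]:
    """Subset rules by ``"all"``, index ranges (``"1-13,15"``) or enzyme names."""
    rules = list(rules)
    sel = selector.strip()
    if sel.lower() == "all" or not sel:
        return rules
    parts = [p.strip() for p in sel.split(",") if p.strip()]
    if all(_re_index(p) for p in parts):
        wanted: set[int] = set()
        for p in parts:
            if "-" in p:
                lo, hi = p.split("-", 1)
                wanted.update(range(int(lo), int(hi) + 1))
            else:
                wanted.add(int(p))
        return [r for r in rules if r.index in wanted]
    names = {p for p in parts}
    known = {r.enzyme for r in rules}
    unknown = names - known
    if unknown:
        raise RuleError(f"unknown enzyme names: {sorted(unknown)}")
    return [r for r in rules if r.enzyme in names]


def _re_index(text: str) -> bool:
    return bool(re.match(r"^\d+(-\d+)?$", text))
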