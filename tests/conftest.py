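"""Shared fixtures and an independent brute-force matching oracle."""

from __future__ import annotations

import itertools

import pytest

import glyconet as gn
from glyconet.linearcode import PatternNode


@pytest.fixture(scope="session")
def rules():
    return gn.load_rule_db()


@pytest.fixture(scope="session")
def rules_by_index(rules):
    return {r.index: r for r in rules}

@pytest.fixture()
def m9():
    return gn.load_fixture("M9")


@pytest.fixture()
def man5():
    return gn.load_fixture("Man5")


# ---------------------------------------------------------------------------
# brute-force pattern-matching oracle
#
# An independent re-implementation of subtree embedding used to cross-check
# the production matcher: it enumerates *every* injective assignment of
# pattern children to subject children explicitly via permutations.
# ---------------------------------------------------------------------------


def _node_ok(p: PatternNode, node) -> bool:
    if p.kind == "ellipsis":
        return True
    if p.kind == "res" and p.symbol != node.residue.symbol:
        return False
    if p.anomer is not None and node.residue.anomer != p.anomer:
        return False
    if p.pos is not None and node.residue.pos != p.pos:
        return False
    if p.anchored and not node.is_leaf:
        return False
    return True


def brute_force_embeddings(p: PatternNode, node, addr=()):
    """All embeddings of ``p`` rooted at ``node`` as target-address sets."""
    if not _node_ok(p, node):
        return []
    pkids = [c for c in p.children if c.kind != "ellipsis"]
    skids = list(node.children)
    if len(pkids) > len(skids):
        return []
    results = []
    for assignment in itertools.permutations(range(len(skids)), len(pkids)):
        sub_results = [[]]
        for pk, si in zip(pkids, assignment):
            child = skids[si]
            caddr = addr + ((child.residue.pos, child.residue.symbol),)
            embeds = brute_force_embeddings(pk, child, caddr)
            if not embeds:
                sub_results = []
                break
            sub_results = [prev + e for prev in sub_results for e in embeds]
        for combo in sub_results:
            results.append(combo + [(id(p), addr)])
    return results


def brute_force_match_anywhere(p: PatternNode, g):
    """Root addresses at which the pattern embeds, with duplicates removed."""
    hits = []
    for addr, node in g.walk():
        if brute_force_embeddings(p, node, addr):
            hits.append(addr)
    return hits
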