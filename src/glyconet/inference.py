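"""Product inference and round-limited forward network construction.

Starting from one or more root glycans, every enzyme rule is applied to every
glycan discovered in the previous round (breadth-first frontier expansion).
New product species join the network with the round index of their first
discovery; reactions between already-known species only add edges.  Expansion
stops at a fixed round cap or when a round yields no new species, whichever
comes first.  Glycans are deduplicated by canonical LinearCode key and
reactions by (substrate, product, enzyme) — several sites or rule rows of the
same enzyme producing the same conversion count as one biochemical step.

With an unconstrained transferase set this expansion never terminates, so a
hard node cap (default 10,000) aborts runaway growth with
:class:`NetworkSizeError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Union

import pandas as pd

from .glycan import Address, Glycan, GlycanError
from .rules import EnzymeRule, HYDROLASE, MatchSite, TRANSFERASE, match_sites

DEFAULT_MAX_NODES = 10_000


class NetworkSizeError(GlycanError):
    """Raised when expansion exceeds the configured node cap."""


class InvalidRoundsError(GlycanError):
    pass


@dataclass(frozen=True)
class Reaction:
    """One enzymatic step: an edge of the reaction network.

    Identity (equality/hash) is the (substrate, product, enzyme) triple;
    ``rule_index`` and ``site`` record the rule row and acceptor/leaving
    residue of the first discovery.
    """

    substrate: str
    product: str
    enzyme: str
    rule_index: int = field(compare=False)
    site: Address = field(compare=False)
    ec: str = field(compare=False, default="")

    def __str__(self) -> str:
        return f"{self.substrate} -[{self.enzyme}]-> {self.product}"


@dataclass
class GlycanNetwork:
    """Deduplicated directed reaction network.

    ``nodes`` maps canonical key -> (glycan, round of first discovery);
    ``edges`` is the set of reactions; ``roots`` lists the starting keys.
    """

    nodes: dict[str, tuple[Glycan, int]]
    edges: list[Reaction]
    roots: list[str]
    rounds_run: int = 0

    @property
    def n_structures(self) -> int:
        return len(self.nodes)

    @property
    def n_reactions(self) -> int:
        return len(self.edges)

    def round_of(self, key: str) -> int:
        return self.nodes[key][1]

    def glycan(self, key: str) -> Glycan:
        return self.nodes[key][0]


def infer_products(
    g: Glycan, rule: EnzymeRule
) -> list[tuple[Glycan, Reaction]]:
    """Apply one rule at every admissible site; one product per site.

    Transferases attach the rule's transferred residue at the acceptor site,
    hydrolases remove the matched terminal residue.  Products are
    deduplicated by canonical key; an empty list means the rule does not act.
    """
    out: list[tuple[Glycan, Reaction]] = []
    seen: set[str] = set()
    for site in match_sites(rule, g):
        if rule.kind == TRANSFERASE:
            product = g.attach(site.address, rule.action_residue)
        else:
            product = g.detach(site.address)
        key = product.canonical
        if key == g.canonical or key in seen:
            continue
        seen.add(key)
        out.append(
            (
                product,
                Reaction(
                    substrate=g.canonical,
                    product=key,
                    enzyme=rule.enzyme,
                    rule_index=rule.index,
                    site=site.address,
                    ec=rule.ec,
                ),
            )
        )
    return out


def forward_network_inference(
    roots: Iterable[Glycan],
    rules: Iterable[EnzymeRule],
    max_rounds: int,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> GlycanNetwork:
    """Breadth-first expansion of the reaction network.

    Round ``k`` applies every rule to every glycan first discovered at round
    ``k - 1``; the roots are round 0.  ``max_rounds = 0`` returns the roots
    only.  Output is deterministic: frontiers are processed in canonical-key
    order and rules in index order.
    """
    roots = list(roots)
    rules = sorted(rules, key=lambda r: r.index)
    if not roots:
        raise InvalidRoundsError("at least one root glycan is required")
    if max_rounds < 0:
        raise InvalidRoundsError(f"max_rounds must be >= 0, got {max_rounds}")

    nodes: dict[str, tuple[Glycan, int]] = {}
    edges: dict[tuple[str, str, str], Reaction] = {}
    for root in roots:
        nodes.setdefault(root.canonical, (root, 0))
    frontier = sorted(nodes)

    rounds_run = 0
    for rnd in range(1, max_rounds + 1):
        if not frontier:
            break
        new_frontier: list[str] = []
        for key in frontier:
            glycan = nodes[key][0]
            for rule in rules:
                for product, reaction in infer_products(glycan, rule):
                    pkey = product.canonical
                    if pkey not in nodes:
                        nodes[pkey] = (product, rnd)
                        new_frontier.append(pkey)
                        if len(nodes) > max_nodes:
                            raise NetworkSizeError(
                                f"network exceeded {max_nodes} glycans at round {rnd}; "
                                "raise max_nodes or lower max_rounds"
                            )
                    edges.setdefault(
                        (reaction.substrate, reaction.product, reaction.enzyme),
                        reaction,
                    )
        rounds_run = rnd
        frontier = sorted(set(new_frontier))

    ordered_edges = [edges[k] for k in sorted(edges)]
    return GlycanNetwork(
        nodes=nodes,
        edges=ordered_edges,
        roots=[r.canonical for r in roots],
        rounds_run=rounds_run,
    )


def prune_network(
    net: GlycanNetwork,
    keep: Union[Callable[[Glycan], bool], Iterable[str]],
) -> GlycanNetwork:
    """Drop nodes failing ``keep`` (a predicate on glycans or a key whitelist)
    together with their incident edges.  Roots must survive."""
    if callable(keep):
        kept = {k for k, (g, _) in net.nodes.items() if keep(g)}
    else:
        kept = set(keep)
    missing_roots = [r for r in net.roots if r not in kept]
    if missing_roots:
        raise GlycanError(f"prune would remove root(s): {missing_roots}")
    nodes = {k: v for k, v in net.nodes.items() if k in kept}
    edges = [e for e in net.edges if e.substrate in kept and e.product in kept]
    return GlycanNetwork(
        nodes=nodes, edges=edges, roots=list(net.roots), rounds_run=net.rounds_run
    )


def network_stats(net: GlycanNetwork) -> pd.DataFrame:
    """Per-round summary of the network.

    One row per round 0..rounds_run with columns:

    ``new_structures``      glycans first discovered that round;
    ``cum_structures``      glycans discovered up to and including the round;
    ``cum_reactions``       reactions whose substrate was discovered in an
                            earlier round (the edges present after that
                            round's expansion);
    ``cum_reactions_known`` same, but dating an edge by when *both* endpoints
                            were known (counts late-found links between
                            earlier species at the later round);
    one column per enzyme   cumulative edge counts per catalysing enzyme.

    Enzyme columns sum to ``cum_reactions_known`` on every row.
    """
    max_round = net.rounds_run
    enzymes = sorted({e.enzyme for e in net.edges})
    records = []
    for rnd in range(0, max_round + 1):
        new = sum(1 for _, (_, r) in net.nodes.items() if r == rnd)
        cum = sum(1 for _, (_, r) in net.nodes.items() if r <= rnd)
        cum_rxn = sum(1 for e in net.edges if net.round_of(e.substrate) < rnd)
        row = {
            "round": rnd,
            "new_structures": new,
            "cum_structures": cum,
            "cum_reactions": cum_rxn,
            "cum_reactions_known": sum(
                1
                for e in net.edges
                if max(net.round_of(e.substrate), net.round_of(e.product)) <= rnd
            ),
        }
        for enz in enzymes:
            row[enz] = sum(
                1
                for e in net.edges
                if e.enzyme == enz
                and max(net.round_of(e.substrate), net.round_of(e.product)) <= rnd
            )
        records.append(row)
    return pd.DataFrame.from_records(records)
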