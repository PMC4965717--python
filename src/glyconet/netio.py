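"""Fixtures and writers for standard network formats.

Inferred networks export to GraphML, SIF, DOT and an RFC-4180 edge CSV so
they can be inspected in Cytoscape, Gephi, Graphviz or a spreadsheet.  Node
identifiers are canonical LinearCode strings; node attributes carry the
discovery round and the monosaccharide composition, edge attributes the
catalysing enzyme, its EC number and the rule row.  Nodes and edges are
written in sorted order, so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Union

import networkx as nx

from .glycan import Glycan, GlycanError
from .inference import GlycanNetwork
from .linearcode import parse_structure

FORMATS = ("graphml", "sif", "dot", "csv-edges")

#: bundled starting structures: the high-mannose precursors entering the
#: Golgi (Man9GlcNAc2 and the common ER-derived Man8 B isomer, which lacks
#: the middle-arm alpha1-2 mannose) and Man5GlcNAc2, the canonical MGAT1
#: substrate.
FIXTURES = {
    "M9": "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
    "M8": "Ma2Ma2Ma3(Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
    "Man5": "Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN",
}


class UnknownFixtureError(GlycanError, KeyError):
    pass


def load_fixture(name: str) -> Glycan:
    """Return a bundled starting glycan (``M9``, ``M8`` or ``Man5``)."""
    try:
        return parse_structure(FIXTURES[name])
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None


def resolve_root(text: str) -> Glycan:
    """A fixture name or a full LinearCode string."""
    if text in FIXTURES:
        return load_fixture(text)
    try:
        return parse_structure(text)
    except GlycanError as exc:
        names = ", ".join(sorted(FIXTURES))
        raise UnknownFixtureError(
            f"{text!r} is neither a fixture name ({names}) "
            f"nor valid LinearCode: {exc}"
        ) from exc


def to_networkx(net: GlycanNetwork) -> "nx.DiGraph":
    """The network as a :class:`networkx.DiGraph` with sorted insertion order."""
    graph = nx.DiGraph()
    for key in sorted(net.nodes):
        glycan, rnd = net.nodes[key]
        comp = glycan.composition()
        graph.add_node(
            key,
            round=rnd,
            composition=" ".join(f"{s}:{comp[s]}" for s in sorted(comp)),
            n_residues=len(glycan),
            is_root=key in net.roots,
        )
    for e in sorted(net.edges, key=lambda e: (e.substrate, e.product, e.enzyme)):
        graph.add_edge(
            e.substrate,
            e.product,
            enzyme=e.enzyme,
            ec=e.ec,
            rule_index=e.rule_index,
        )
    return graph


def export_network(net: GlycanNetwork, fmt: str, path: Union[str, Path]) -> None:
    """Write the network to ``path`` in one of :data:`FORMATS`.

    Output is deterministic (sorted nodes/edges, LF line endings).
    """
    if fmt not in FORMATS:
        raise GlycanError(f"unknown format {fmt!r}; choose from {FORMATS}")
    path = Path(path)
    try:
        if fmt == "graphml":
            graph = to_networkx(net)
            nx.write_graphml(graph, path)
        elif fmt == "sif":
            path.write_text(_render_sif(net), encoding="utf-8")
        elif fmt == "dot":
            path.write_text(_render_dot(net), encoding="utf-8")
        else:
            path.write_text(_render_edge_csv(net), encoding="utf-8", newline="")
    except OSError as exc:
        raise GlycanError(f"cannot write {path}: {exc}") from exc


def _sorted_edges(net: GlycanNetwork):
    return sorted(net.edges, key=lambda e: (e.substrate, e.product, e.enzyme))


def _render_sif(net: GlycanNetwork) -> str:
    lines = [f"{e.substrate}\t{e.enzyme}\t{e.product}" for e in _sorted_edges(net)]
    # isolated nodes still need a line of their own
    touched = {e.substrate for e in net.edges} | {e.product for e in net.edges}
    lines.extend(key for key in sorted(net.nodes) if key not in touched)
    return "\n".join(lines) + "\n"


def _render_dot(net: GlycanNetwork) -> str:
    out = ["digraph glycan_network {"]
    for key in sorted(net.nodes):
        rnd = net.nodes[key][1]
        out.append(f'    "{key}" [round={rnd}];')
    for e in _sorted_edges(net):
        out.append(f'    "{e.substrate}" -> "{e.product}" [label="{e.enzyme}"];')
    out.append("}")
    return "\n".join(out) + "\n"


def _render_edge_csv(net: GlycanNetwork) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["substrate", "product", "enzyme", "ec", "rule_index", "substrate_round", "product_round"]
    )
    for e in _sorted_edges(net):
        writer.writerow(
            [
                e.substrate,
                e.product,
                e.enzyme,
                e.ec,
                e.rule_index,
                net.round_of(e.substrate),
                net.round_of(e.product),
            ]
        )
    return buf.getvalue()
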