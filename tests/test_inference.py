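"""Unit tests for product inference and forward network construction."""

import pytest

import glyconet as gn
from glyconet import (
    GlycanError,
    InvalidRoundsError,
    NetworkSizeError,
    forward_network_inference,
    infer_products,
    network_stats,
    parse_structure,
    prune_network,
    select_rules,
)

RUNAWAY_DB = """\
index,enzyme,ec,kind,substrate_pattern,product_pattern,constraint,\
subst_min_struct,subst_max_struct,subst_na_branch,subst_na_struct,\
subst_na_residue,target_branch,target_na_branch,is_terminal_target,source_note
1,GalT,1.1.1.1,GT,(GN,(Ab4GN,,,,,,,,,,
2,GnT,1.1.1.2,GT,(Ab4GN,(GNb3Ab4GN,,,,,,,,,,
"""


@pytest.fixture()
def runaway_rules(tmp_path):
    path = tmp_path / "runaway.csv"
    path.write_text(RUNAWAY_DB)
    return gn.load_rule_db(path)


def test_infer_products_one_per_site(rules_by_index, m9):
    products = infer_products(m9, rules_by_index[1])
    assert len(products) == 2  # two trimmable alpha1-2 mannoses
    for product, reaction in products:
        assert reaction.substrate == m9.canonical
        assert reaction.product == product.canonical
        assert reaction.enzyme == "ManI"
        assert product.composition()["M"] == 8


def test_infer_products_empty_when_rule_silent(rules_by_index, man5):
    assert infer_products(man5, rules_by_index[5]) == []


def test_empty_rule_set_yields_roots_only(m9):
    net = forward_network_inference([m9], [], max_rounds=10)
    assert net.n_structures == 1
    assert net.n_reactions == 0
    assert net.roots == [m9.canonical]


def test_zero_rounds_yields_roots_only(rules, m9):
    net = forward_network_inference([m9], rules, max_rounds=0)
    assert net.n_structures == 1 and net.n_reactions == 0


def test_invalid_rounds_and_empty_roots(rules, m9):
    with pytest.raises(InvalidRoundsError):
        forward_network_inference([m9], rules, max_rounds=-1)
    with pytest.raises(InvalidRoundsError):
        forward_network_inference([], rules, max_rounds=3)


def test_fixpoint_termination(rules, m9):
    # 1-10,12,13 is finite: without iGnT no new acceptor GlcNAc appears
    subset = select_rules(rules, "1-10,12,13")
    capped = forward_network_inference([m9], subset, max_rounds=8)
    huge = forward_network_inference([m9], subset, max_rounds=500)
    assert huge.rounds_run < 500  # reached fixpoint, did not loop forever
    assert huge.n_structures >= capped.n_structures


def test_node_cap_aborts_runaway_growth(runaway_rules):
    root = parse_structure("GNb2Ma3Mb4GNb4GN")
    with pytest.raises(NetworkSizeError):
        forward_network_inference([root], runaway_rules, 50, max_nodes=10)


def test_round_invariants(rules, m9):
    net = forward_network_inference([m9], rules, max_rounds=7)
    for root in net.roots:
        assert net.round_of(root) == 0
    for e in net.edges:
        assert e.substrate in net.nodes and e.product in net.nodes
        assert net.round_of(e.product) <= net.round_of(e.substrate) + 1
    # no duplicate edges
    keys = [(e.substrate, e.product, e.enzyme) for e in net.edges]
    assert len(keys) == len(set(keys))


def test_composition_conserved_along_every_edge(rules, m9):
    net = forward_network_inference([m9], rules, max_rounds=7)
    for e in net.edges:
        sub = net.glycan(e.substrate).composition()
        prod = net.glycan(e.product).composition()
        gained = prod - sub
        lost = sub - prod
        assert sum(gained.values()) + sum(lost.values()) == 1, str(e)


def test_oracle_equivalence_on_toy_rule_set(rules, man5):
    """BFS inference matches an independent exhaustive depth-limited search."""
    toy = select_rules(rules, "6,12,13")  # MGAT1, b4GalT, a3SiaT
    depth = 4
    net = forward_network_inference([man5], toy, max_rounds=depth)

    reachable = {man5.canonical: 0}
    frontier = {man5.canonical: man5}
    for d in range(1, depth + 1):
        nxt = {}
        for g in frontier.values():
            for rule in toy:
                for product, _ in infer_products(g, rule):
                    if product.canonical not in reachable:
                        reachable[product.canonical] = d
                        nxt[product.canonical] = product
        frontier = nxt
    assert {k: r for k, (_, r) in net.nodes.items()} == reachable


def test_prune_identity_and_root_protection(rules, m9):
    net = forward_network_inference([m9], select_rules(rules, "1-13"), 7)
    same = prune_network(net, lambda g: True)
    assert same.n_structures == net.n_structures
    assert same.n_reactions == net.n_reactions
    with pytest.raises(GlycanError):
        prune_network(net, lambda g: g.canonical != m9.canonical)


def test_prune_drops_nodes_and_incident_edges(rules, m9):
    net = forward_network_inference([m9], select_rules(rules, "1-13"), 7)
    # keep only pure high-mannose species (no antennal GlcNAc)
    kept = prune_network(net, lambda g: g.composition()["GN"] == 2)
    assert 1 < kept.n_structures < net.n_structures
    keys = set()
    for k in net.nodes:
        if net.glycan(k).composition()["GN"] == 2:
            keys.add(k)
    assert set(kept.nodes) == keys
    for e in kept.edges:
        assert e.substrate in keys and e.product in keys


def test_prune_accepts_whitelist(rules, m9):
    net = forward_network_inference([m9], select_rules(rules, "1"), 2)
    kept = prune_network(net, set(net.nodes))
    assert kept.n_structures == net.n_structures


def test_network_stats_trivial(m9):
    net = forward_network_inference([m9], [], max_rounds=5)
    stats = network_stats(net)
    assert set(stats["cum_structures"]) == {1}
    assert set(stats["cum_reactions"]) == {0}


def test_network_stats_monotone_and_consistent(rules, m9):
    net = forward_network_inference([m9], rules, max_rounds=7)
    stats = network_stats(net)
    assert list(stats["round"]) == list(range(0, net.rounds_run + 1))
    for col in ("cum_structures", "cum_reactions", "cum_reactions_known"):
        assert stats[col].is_monotonic_increasing
    assert stats["new_structures"].sum() == net.n_structures
    last = stats.iloc[-1]
    assert last["cum_structures"] == net.n_structures
    assert last["cum_reactions"] == net.n_reactions
    enzymes = sorted({e.enzyme for e in net.edges})
    assert (stats[enzymes].sum(axis=1) == stats["cum_reactions_known"]).all()
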