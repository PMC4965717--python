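"""Unit tests for the rule database, matcher and specificity predicates."""

import textwrap

import pytest

from glyconet import (
    RuleError,
    load_rule_db,
    match_sites,
    parse_pattern,
    parse_structure,
    select_rules,
)
from glyconet.rules import (
    HYDROLASE,
    TRANSFERASE,
    contains,
    eval_constraint,
    match_anywhere,
    match_at,
)
from glyconet.linearcode import parse_constraint

from conftest import brute_force_match_anywhere

BIANTENNARY = "GNb2Ma3(GNb2Ma6)Mb4GNb4GN"


# -- matcher -----------------------------------------------------------------


def test_match_at_rooted_embedding(man5):
    p = parse_pattern("Ma3(Ma6)Mb4")
    core = man5.node_at(((4, "GN"), (4, "M")))
    assert match_at(p, core, ((4, "GN"), (4, "M")))
    assert not match_at(p, man5)  # root is GN, not Mb4


def test_match_allows_extra_subject_branches(m9):
    # Mb4 with an alpha3 branch embeds although M9's core also has alpha6
    p = parse_pattern("Ma3Mb4")
    assert match_anywhere(p, m9)


def test_anchored_pattern_requires_leaf(m9, man5):
    p = parse_pattern("(Ma2Ma")
    assert match_anywhere(p, m9)
    assert not match_anywhere(p, man5)  # Man5 has no terminal alpha1-2 Man


def test_matcher_agrees_with_brute_force_on_rule_patterns(rules, m9, man5):
    subjects = [
        m9,
        man5,
        parse_structure(BIANTENNARY),
        parse_structure("NNa3Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4(Fa6)GN"),
        parse_structure("Fa2Ab3(Fa4)GNb2Ma3(Ma6)Mb4GNb4GN"),
    ]
    for rule in rules:
        for g in subjects:
            fast = sorted({a for a, _ in match_anywhere(rule.substrate_pattern, g)})
            slow = sorted(set(brute_force_match_anywhere(rule.substrate_pattern, g)))
            assert fast == slow, f"rule {rule.index} on {g}"


def test_contains_rooted():
    big = parse_structure(BIANTENNARY)
    assert contains(big, parse_structure("Mb4GNb4GN"))
    assert contains(big, parse_structure(BIANTENNARY))
    assert not contains(big, parse_structure("Fa6GN"))
    assert not contains(parse_structure("Mb4GNb4GN"), big)


# -- constraint atoms --------------------------------------------------------


def test_gnbis_atom():
    bisected = parse_structure("GNb2Ma3(GNb4)Mb4GNb4GN")
    plain = parse_structure("GNb2Ma3Mb4GNb4GN")
    expr = parse_constraint("Gnbis")
    assert eval_constraint(expr, bisected, ())
    assert not eval_constraint(expr, plain, ())


def test_ab_atom():
    gal = parse_structure("Ab4GNb2Ma3Mb4GNb4GN")
    expr = parse_constraint("Ab")
    assert eval_constraint(expr, gal, ())
    assert not eval_constraint(expr, parse_structure(BIANTENNARY), ())


def test_branch_atom():
    g = parse_structure(BIANTENNARY)
    assert eval_constraint(parse_constraint("GNb2 |Ma3"), g, ())
    no_a3_antenna = parse_structure("GNb2Ma6(Ma3)Mb4GNb4GN")
    assert not eval_constraint(parse_constraint("GNb2 |Ma3"), no_a3_antenna, ())


def test_target_path_atom(m9):
    # the middle-arm alpha1-2 Man: Ma2 on Ma3 on Ma6
    middle = ((4, "GN"), (4, "M"), (6, "M"), (3, "M"), (2, "M"))
    outer = ((4, "GN"), (4, "M"), (3, "M"), (2, "M"), (2, "M"))
    expr = parse_constraint("_Ma2Ma3Ma6")
    assert eval_constraint(expr, m9, middle)
    assert not eval_constraint(expr, m9, outer)


def test_target_branch_atom(m9):
    a3_arm_leaf = ((4, "GN"), (4, "M"), (3, "M"), (2, "M"), (2, "M"))
    a6_arm_leaf = ((4, "GN"), (4, "M"), (6, "M"), (6, "M"), (2, "M"))
    expr = parse_constraint("_Ma3 |Mb4")
    assert eval_constraint(expr, m9, a3_arm_leaf)
    assert not eval_constraint(expr, m9, a6_arm_leaf)


# -- database ----------------------------------------------------------------


def test_bundled_db_integrity(rules):
    assert len(rules) == 27
    assert len({r.enzyme for r in rules}) == 22
    import re

    for r in rules:
        assert re.match(r"^\d+\.\d+\.\d+\.\d+$", r.ec), r
        assert r.kind in (TRANSFERASE, HYDROLASE)
    assert [r.index for r in rules] == list(range(1, 28))


def test_derived_actions(rules_by_index):
    r5 = rules_by_index[5]  # core fucosylation
    assert r5.resfuncgroup == "F" and r5.link_fg == "a6"
    assert r5.res_att2fg == "GN"
    r8 = rules_by_index[8]  # bisecting GlcNAc onto the core beta-Man
    assert r8.resfuncgroup == "GN" and r8.link_fg == "b4"
    assert r8.res_att2fg == "M" and r8.link_res_att2fg == "b4"
    r1 = rules_by_index[1]  # mannosidase removes an alpha1-2 Man
    assert r1.kind == HYDROLASE
    assert r1.resfuncgroup == "M" and r1.link_fg == "a2"
    assert r1.res_att2fg is None


def _write_db(tmp_path, body):
    path = tmp_path / "rules.csv"
    header = (
        "index,enzyme,ec,kind,substrate_pattern,product_pattern,constraint,"
        "subst_min_struct,subst_max_struct,subst_na_branch,subst_na_struct,"
        "subst_na_residue,target_branch,target_na_branch,is_terminal_target,"
        "source_note"
    )
    path.write_text(header + "\n" + textwrap.dedent(body))
    return path


def test_load_rejects_bad_ec(tmp_path):
    path = _write_db(tmp_path, "1,X,9.9.9,GT,(GN,(Ab4GN,,,,,,,,,,\n")
    with pytest.raises(RuleError):
        load_rule_db(path)


def test_load_rejects_duplicate_index(tmp_path):
    path = _write_db(
        tmp_path,
        "1,X,1.1.1.1,GT,(GN,(Ab4GN,,,,,,,,,,\n"
        "1,Y,1.1.1.2,GT,(GN,(Ab3GN,,,,,,,,,,\n",
    )
    with pytest.raises(RuleError):
        load_rule_db(path)


def test_load_rejects_bad_kind(tmp_path):
    path = _write_db(tmp_path, "1,X,1.1.1.1,ZZ,(GN,(Ab4GN,,,,,,,,,,\n")
    with pytest.raises(RuleError):
        load_rule_db(path)


def test_load_rejects_multi_residue_diff(tmp_path):
    path = _write_db(tmp_path, "1,X,1.1.1.1,GT,(GN,(NNa3Ab4GN,,,,,,,,,,\n")
    with pytest.raises(RuleError):
        load_rule_db(path)


def test_load_empty_db_warns(tmp_path, caplog):
    path = tmp_path / "rules.csv"
    path.write_text(
        "index,enzyme,ec,kind,substrate_pattern,product_pattern,constraint,"
        "subst_min_struct,subst_max_struct,subst_na_branch,subst_na_struct,"
        "subst_na_residue,target_branch,target_na_branch,is_terminal_target,"
        "source_note\n"
    )
    with caplog.at_level("WARNING"):
        assert load_rule_db(path) == []
    assert any("empty" in rec.message for rec in caplog.records)


def test_select_rules(rules):
    assert len(select_rules(rules, "all")) == 27
    subset = select_rules(rules, "1-13")
    assert [r.index for r in subset] == list(range(1, 14))
    assert len({r.enzyme for r in subset}) == 11
    assert [r.index for r in select_rules(rules, "1-3,27")] == [1, 2, 3, 27]
    fut = select_rules(rules, "FUT8")
    assert {r.enzyme for r in fut} == {"FUT8"}
    with pytest.raises(RuleError):
        select_rules(rules, "NotAnEnzyme")


# -- specificity predicates on real rules ------------------------------------


def test_fut8_requires_biantennary_core(rules_by_index):
    r5 = rules_by_index[5]
    hybrid = parse_structure("GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN")
    assert not match_sites(r5, hybrid)
    assert len(match_sites(r5, parse_structure(BIANTENNARY))) == 1


def test_fut8_blocked_by_bisecting_and_gal(rules_by_index):
    r5 = rules_by_index[5]
    bisected = parse_structure("GNb2Ma3(GNb2Ma6)(GNb4)Mb4GNb4GN")
    galactosylated = parse_structure("Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4GN")
    assert not match_sites(r5, bisected)
    assert not match_sites(r5, galactosylated)


def test_mani_spares_middle_arm(rules_by_index, m9):
    sites = match_sites(rules_by_index[1], m9)
    middle = ((4, "GN"), (4, "M"), (6, "M"), (3, "M"), (2, "M"))
    assert len(sites) == 2
    assert middle not in {s.address for s in sites}


def test_manii_waits_for_mani(rules_by_index):
    r3 = rules_by_index[3]
    ready = parse_structure("GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN")
    still_trimming = parse_structure("GNb2Ma3(Ma3(Ma2Ma6)Ma6)Mb4GNb4GN")
    assert match_sites(r3, ready)
    assert not match_sites(r3, still_trimming)


def test_transferase_skips_occupied_position(rules_by_index):
    r13 = rules_by_index[13]  # alpha2-3 sialylation of Ab4GN
    free = parse_structure("Ab4GN")
    taken = parse_structure("NNa3Ab4GN")
    assert len(match_sites(r13, free)) == 1
    assert not match_sites(r13, taken)
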