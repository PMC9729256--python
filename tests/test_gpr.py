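import itertools

import numpy as np
import pytest
import sympy
from sympy.logic.boolalg import And as SymAnd  # noqa: F401 (sanity import)

from orthogem import parse_rule, evaluate_rule, substitute_rule
from orthogem.gpr import And, Gene, GprParseError, Or
from orthogem.orthology import OrthogroupTable


# --- independent random rule generator (test-side oracle) --------------------


def random_rule_text(rng, genes, max_depth=3):
    """Build nested rule text with an independent tuple-tree evaluator."""

    def build(depth):
        if depth == 0 or rng.random() < 0.4:
            g = str(rng.choice(genes))
            return g, g
        op = "and" if rng.random() < 0.5 else "or"
        n = int(rng.integers(2, 4))
        parts = [build(depth - 1) for _ in range(n)]
        text = f" {op} ".join(
            f"({t})" if " " in t else t for t, _ in parts
        )
        return text, (op, tuple(tree for _, tree in parts))

    return build(max_depth)


def eval_tree(tree, present):
    if isinstance(tree, str):
        return tree in present
    op, children = tree
    results = [eval_tree(c, present) for c in children]
    return all(results) if op == "and" else any(results)


# --- parsing ----------------------------------------------------------------


def test_or_of_two_genes():
    rule = parse_rule("g1 or g2")
    assert rule.tree == Or((Gene("g1"), Gene("g2")))


def test_and_binds_tighter_than_or():
    rule = parse_rule("g1 and g2 or g3")
    assert rule.tree == Or((And((Gene("g1"), Gene("g2"))), Gene("g3")))


def test_case_insensitive_operators_and_whitespace():
    assert parse_rule("g1 AND  g2").tree == parse_rule("g1 and g2").tree
    assert parse_rule(" g1  Or g2 ").tree == parse_rule("g1 or g2").tree


def test_empty_text_is_no_rule():
    assert parse_rule("") is None
    assert parse_rule("   ") is None


@pytest.mark.parametrize("bad", ["(g1 or g2", "g1 and", "and g1", "g1 or or g2"])
def test_malformed_rules_raise_with_position(bad):
    with pytest.raises(GprParseError):
        parse_rule(bad)


def test_print_parse_round_trip_on_random_rules():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 9)]
    for _ in range(200):
        text, _ = random_rule_text(rng, genes)
        rule = parse_rule(text)
        assert parse_rule(rule.to_text()).tree == rule.tree


# --- evaluation -------------------------------------------------------------


def test_or_true_with_one_gene():
    assert evaluate_rule(parse_rule("g1 or g2"), {"g1"}) is True


def test_and_false_with_one_gene():
    assert evaluate_rule(parse_rule("g1 and g2"), {"g1"}) is False


def test_empty_rule_is_contract_violation():
    with pytest.raises(ValueError):
        evaluate_rule(None, {"g1"})


def test_exhaustive_truth_tables_up_to_four_genes():
    """Agreement with direct truth-table enumeration over all 2^4 sets."""
    rng = np.random.default_rng(11)
    genes = ["g1", "g2", "g3", "g4"]
    for _ in range(100):
        text, tree = random_rule_text(rng, genes)
        rule = parse_rule(text)
        for r in range(len(genes) + 1):
            for subset in itertools.combinations(genes, r):
                present = set(subset)
                assert rule.evaluate(present) == eval_tree(tree, present)


def test_agreement_with_sympy_boolean_oracle():
    """Second independent route: sympy's boolean algebra on the same text."""
    rng = np.random.default_rng(13)
    genes = ["g1", "g2", "g3", "g4", "g5"]
    syms = {g: sympy.Symbol(g) for g in genes}
    for _ in range(50):
        text, _ = random_rule_text(rng, genes)
        expr = sympy.parsing.sympy_parser.parse_expr(
            text.replace(" and ", " & ").replace(" or ", " | "),
            local_dict=syms, evaluate=False,
        )
        rule = parse_rule(text)
        for subset in itertools.chain.from_iterable(
            itertools.combinations(genes, r) for r in range(6)
        ):
            present = set(subset)
            expected = bool(expr.subs({syms[g]: g in present for g in genes}))
            assert rule.evaluate(present) == expected


def test_evaluation_is_monotone():
    rng = np.random.default_rng(17)
    genes = [f"g{i}" for i in range(1, 6)]
    for _ in range(100):
        text, _ = random_rule_text(rng, genes)
        rule = parse_rule(text)
        present = {g for g in genes if rng.random() < 0.5}
        extra = present | {str(rng.choice(genes))}
        if rule.evaluate(present):
            assert rule.evaluate(extra)


# --- substitution -----------------------------------------------------------


def _table(mapping, genomes=("REF", "T")):
    """mapping: ref gene -> list of target genes ('' entries ignored)."""
    ogs = {}
    for i, (gene, targets) in enumerate(sorted(mapping.items())):
        ogs[f"OG{i:04d}"] = {"REF": [gene], "T": list(targets)}
    return OrthogroupTable(orthogroups=ogs, genomes=list(genomes))


def test_co_ortholog_or_expansion():
    rule = parse_rule("gA")
    table = _table({"gA": ["t1", "t2"]})
    new, report = substitute_rule(rule, table, "REF", "T")
    assert new.tree == Or((Gene("t1"), Gene("t2")))
    assert report.substitutions[0].status == "mapped"


def test_empty_orthogroup_gives_false_rule():
    rule = parse_rule("gA")
    table = _table({"gA": []})
    new, report = substitute_rule(rule, table, "REF", "T")
    assert new.is_false
    assert report.substitutions[0].status == "absent-in-target"


def test_unmapped_gene_reported_and_false():
    rule = parse_rule("gA or gB")
    table = _table({"gB": ["t9"]})  # gA in no orthogroup
    new, report = substitute_rule(rule, table, "REF", "T")
    assert report.unmapped_genes == ["gA"]
    assert new.tree == Gene("t9")  # false branch pruned, structure kept


def test_and_rule_shared_orthogroup_sets_curation_flag():
    rule = parse_rule("gA and gB")
    ogs = {"OG1": {"REF": ["gA", "gB"], "T": ["t1"]}}
    table = OrthogroupTable(orthogroups=ogs, genomes=["REF", "T"])
    _, report = substitute_rule(rule, table, "REF", "T")
    assert report.and_shared_orthogroup_flag is True


def test_substitution_evaluation_commutation_exhaustive():
    """evaluate(substituted, target genes) == evaluate(original, induced
    reference presence), for random rules <= 5 genes and random loss maps."""
    rng = np.random.default_rng(23)
    genes = [f"g{i}" for i in range(1, 6)]
    for _ in range(500):
        text, _ = random_rule_text(rng, genes)
        rule = parse_rule(text)
        mapping = {}
        for g in genes:
            n_targets = int(rng.integers(0, 3))
            mapping[g] = [f"t_{g}_{k}" for k in range(n_targets)]
        table = _table(mapping)
        target_genes = {t for ts in mapping.values() for t in ts}
        induced = {g for g in genes if mapping[g]}
        new, _ = substitute_rule(rule, table, "REF", "T")
        left = (not new.is_false) and new.evaluate(target_genes)
        right = rule.evaluate(induced)
        assert left == right


# --- hypothesis property tests ------------------------------------------------

import hypothesis.strategies as st
from hypothesis import given, settings

from orthogem.gpr import GprRule

_genes = st.sampled_from([f"g{i}" for i in range(1, 7)])
_trees = st.recursive(
    st.builds(Gene, _genes),
    lambda kids: st.builds(And, st.tuples(kids, kids))
    | st.builds(Or, st.tuples(kids, kids)),
    max_leaves=12,
)


@settings(max_examples=150, derandomize=True)
@given(_trees)
def test_property_print_parse_identity(tree):
    rule = GprRule(tree=tree)
    assert parse_rule(rule.to_text()).tree == tree


@settings(max_examples=150, derandomize=True)
@given(_trees, st.sets(_genes), _genes)
def test_property_monotone_evaluation(tree, present, extra):
    rule = GprRule(tree=tree)
    if rule.evaluate(present):
        assert rule.evaluate(present | {extra})
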