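import itertools

import numpy as np
import pytest

from cohortqa import coordination_rewrite, default_grammar, parse, recognizes
from cohortqa.concepts import ConceptType
from cohortqa.grammar import TERMINALS, Grammar
from cohortqa.linking import Annotation, Candidate, TypedSequence, TypedToken

from conftest import SEQ_14, SEQ_16


def closure_yields(grammar, max_len):
    """Independent oracle: all derivable terminal strings per symbol, by
    bottom-up closure (no chart, no spans)."""
    yields = {t: {(t,)} for t in TERMINALS}
    for nt in grammar.nonterminals:
        yields.setdefault(nt, set())
    changed = True
    while changed:
        changed = False
        for p in grammar.productions:
            pools = [yields.get(s, set()) for s in p.rhs]
            if any(not pool for pool in pools):
                continue
            for combo in itertools.product(*pools):
                s = tuple(x for part in combo for x in part)
                if len(s) <= max_len and s not in yields[p.lhs]:
                    yields[p.lhs].add(s)
                    changed = True
    return yields


def test_grammar_matches_bundled_file():
    g = default_grammar()
    g2 = Grammar.load()
    assert g.productions == g2.productions
    assert g.start == "S"
    assert g.terminals <= TERMINALS
    assert g.nonterminals == {"S", "Condition", "RelationCondition",
                              "PropertyCondition", "PropertyValue", "NumericValue",
                              "NumericRange", "TimeBlock", "QueryItem"}


@pytest.mark.parametrize("seq, symbol, derivable", [
    (["Property", "StatisticOperator"], "S", True),          # minimal query item
    (["Relation", "Instance"], "RelationCondition", True),
    (["Number", "RangeSeparator", "Number"], "NumericRange", True),
    (["Relation", "Instance", "Class", "StatisticOperator"], "S", True),
    (["Relation", "Instance", "LogicalOperator", "Instance"], "S", False),
    (["TimeOperator"], "S", False),
])
def test_example_derivations(seq, symbol, derivable):
    g = default_grammar()
    from cohortqa.grammar import _derivable
    table = _derivable(seq, g)
    assert table.get((symbol, 0, len(seq)), False) is derivable


def test_canonical_sequences_parse():
    assert recognizes(SEQ_14)
    assert recognizes(SEQ_16)


def test_forest_yields_preserve_input():
    seq = SEQ_16
    forest = parse(seq)
    assert forest
    for tree in forest.trees:
        assert tree.yield_types() == seq
        assert tree.yield_indices() == list(range(len(seq)))


def test_empty_sequence_is_a_parameter_error():
    with pytest.raises(ValueError):
        parse([])


def test_forest_cap_truncates_ambiguity():
    seq = ["Relation", "Instance"] + \
        ["LogicalOperator", "Relation", "Instance"] * 5 + ["StatisticOperator"]
    forest = parse(seq, cap=3)
    assert len(forest.trees) == 3 and forest.truncated


def test_chart_parser_equals_closure_oracle_up_to_length_4():
    g = default_grammar()
    derivable = closure_yields(g, 4)["S"]
    terms = sorted(TERMINALS)
    for L in range(1, 5):
        for seq in itertools.product(terms, repeat=L):
            assert recognizes(list(seq), g) == (seq in derivable), seq


def top_down_derives(grammar):
    """Second independent oracle: memoized top-down expansion.  Every
    symbol yields at least one terminal, so sentential forms longer than
    the target sequence are pruned."""
    from functools import lru_cache
    by_lhs: dict[str, list] = {}
    for p in grammar.productions:
        by_lhs.setdefault(p.lhs, []).append(p)

    @lru_cache(maxsize=None)
    def rec(symbols, sub):
        if not symbols:
            return not sub
        if len(symbols) > len(sub):
            return False
        head, rest = symbols[0], symbols[1:]
        if head in TERMINALS:
            return bool(sub) and sub[0] == head and rec(rest, sub[1:])
        return any(rec(p.rhs + rest, sub) for p in by_lhs[head])

    return lambda seq: rec((grammar.start,), tuple(seq))


def random_sentences(grammar, rng, n, max_len):
    """Random derivations from S (shortest-expansion fallback bounds size)."""
    by_lhs: dict[str, list] = {}
    for p in grammar.productions:
        by_lhs.setdefault(p.lhs, []).append(p)
    out = []
    for _ in range(n * 4):
        forms = ["S"]
        for _ in range(60):
            idx = next((i for i, s in enumerate(forms) if s not in TERMINALS), None)
            if idx is None:
                break
            prods = by_lhs[forms[idx]]
            if len(forms) >= max_len:  # steer toward short expansions
                prods = sorted(prods, key=lambda p: len(p.rhs))[:1]
            else:
                prods = [prods[int(rng.integers(len(prods)))]]
            forms = forms[:idx] + list(prods[0].rhs) + forms[idx + 1:]
        if all(s in TERMINALS for s in forms) and len(forms) <= max_len:
            out.append(tuple(forms))
        if len(out) >= n:
            break
    return out


def test_chart_parser_matches_oracle_on_random_length_8_sequences():
    g = default_grammar()
    oracle = top_down_derives(g)
    terms = sorted(TERMINALS)
    rng = np.random.default_rng(42)
    cases = [tuple(terms[i] for i in rng.integers(0, len(terms), size=L))
             for L in range(1, 9) for _ in range(40)]
    positives = random_sentences(g, rng, 60, 8)
    assert positives  # both labels must occur
    for seq in cases + positives:
        assert recognizes(list(seq), g) == oracle(seq), seq


# ---------------------------------------------------------------------------
# coordination rewrite
# ---------------------------------------------------------------------------

def _seq(types):
    tokens = []
    for i, t in enumerate(types):
        ct = ConceptType(t)
        tokens.append(TypedToken(ct, Annotation(f"w{i}", [Candidate(f"w{i}", ct, 1.0)])))
    return TypedSequence(tokens)


def test_bare_conjunct_receives_governing_relation():
    out = coordination_rewrite(_seq(
        ["Relation", "Instance", "LogicalOperator", "Instance"]))
    assert len(out) == 1
    assert out[0].types == ["Relation", "Instance", "LogicalOperator",
                            "Relation", "Instance"]
    assert out[0].tokens[3].synthetic
    assert out[0].tokens[3].annotation.token == "w0"  # the governing relation


def test_not_bearing_variant():
    out = coordination_rewrite(_seq(
        ["Relation", "Instance", "LogicalOperator", "Not", "Instance"]))
    assert out[0].types == ["Relation", "Instance", "LogicalOperator", "Not",
                            "Relation", "Instance"]


def test_already_complete_coordination_is_left_alone():
    out = coordination_rewrite(_seq(
        ["Relation", "Instance", "LogicalOperator", "Relation", "Instance"]))
    assert out == []


def test_conjunct_chain_rewrites_to_fixpoint_and_parses():
    out = coordination_rewrite(_seq(
        ["Relation", "Instance", "LogicalOperator", "Instance",
         "LogicalOperator", "Instance", "Class", "StatisticOperator"]))
    assert out[0].types == ["Relation", "Instance",
                            "LogicalOperator", "Relation", "Instance",
                            "LogicalOperator", "Relation", "Instance",
                            "Class", "StatisticOperator"]
    assert len(out[0]) > 8  # rewriting strictly lengthens
    assert recognizes(out[0].types)
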