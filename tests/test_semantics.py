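import numpy as np
import pytest

from cohortqa import (AttrTriple, Cmp, EnumV, EventTriple, GeneratorConfig, Group,
                      Lexicon, LexiconEntry, Pipeline, QuerySpec, SemanticTree,
                      TimeFilter, TimeJoin, UnanswerableError, attach_time,
                      default_schema, disambiguate, generate_graph, parse_serialized,
                      random_tree, serialize, tree_census)
from cohortqa.concepts import ConceptType
from cohortqa.kg_store import DataGraph, Node, PatientGraph

from conftest import CANONICAL_EXPR, CANONICAL_ZH, SEQ_14


# ---------------------------------------------------------------------------
# canonical worked example
# ---------------------------------------------------------------------------

def test_canonical_question_serializes_to_printed_expression(zh_pipeline):
    tree, answer = zh_pipeline.interpret(CANONICAL_ZH)
    assert answer.covered
    assert serialize(tree) == CANONICAL_EXPR


def test_canonical_tree_census_is_eight_nodes_nine_edges(zh_pipeline):
    tree, _ = zh_pipeline.interpret(CANONICAL_ZH)
    assert tree_census(tree) == (8, 9)


def test_minimal_count_tree_census():
    tree = SemanticTree([], QuerySpec("count"))
    assert serialize(tree) == "<patient, count, ?>"
    assert tree_census(tree) == (2, 1)


def test_two_conjoined_triples_census():
    tree = SemanticTree([
        EventTriple("patient", "suffer", "hyperglycemia", "disease", "d0"),
        EventTriple("patient", "take", "aspirin", "drug", "r0"),
    ], QuerySpec("count"))
    assert tree_census(tree) == (4, 3)


# ---------------------------------------------------------------------------
# serialization round trip
# ---------------------------------------------------------------------------

def test_single_triple_count_serialization():
    tree = SemanticTree(
        [EventTriple("patient", "suffer", "hyperglycemia", "disease", "d0")],
        QuerySpec("count"))
    assert serialize(tree) == "<patient, suffer, hyperglycemia> <patient, count, ?>"


def test_serialize_parse_round_trip_is_fixpoint_on_canonical(zh_pipeline):
    tree, _ = zh_pipeline.interpret(CANONICAL_ZH)
    text = serialize(tree)
    assert serialize(parse_serialized(text)) == text
    assert tree_census(parse_serialized(text)) == tree_census(tree)


def test_serialize_parse_round_trip_on_random_trees():
    g = generate_graph(GeneratorConfig(n_patients=10, seed=9))
    rng = np.random.default_rng(5)
    for _ in range(100):
        tree = random_tree(g, rng)
        text = serialize(tree)
        assert serialize(parse_serialized(text)) == text


# ---------------------------------------------------------------------------
# operator precedence
# ---------------------------------------------------------------------------

def _depths(el, d=0, out=None):
    out = out if out is not None else {"not": [], "logic": [], "time": []}
    if isinstance(el, (EventTriple, AttrTriple)):
        if el.negated:
            out["not"].append(d)
    elif isinstance(el, Group):
        out["logic"].append(d)
        for c in el.children:
            _depths(c, d + 1, out)
    elif isinstance(el, TimeJoin):
        out["time"].append(d)
        _depths(el.left, d + 1, out)
        _depths(el.right, d + 1, out)
    return out


def test_precedence_not_inside_logic_inside_time(zh_pipeline):
    tree, _ = zh_pipeline.interpret(CANONICAL_ZH)
    for el in tree.conditions:
        d = _depths(el)
        if d["time"] and d["logic"]:
            assert min(d["logic"]) > min(d["time"])
        if d["logic"] and d["not"]:
            assert min(d["not"]) > min(d["logic"])


# ---------------------------------------------------------------------------
# disambiguation
# ---------------------------------------------------------------------------

def _coldrine_pipeline():
    """Mini graph for the drug/disease homonym example: the token links to
    both a disease ('cold') and a drug ('Coldrine capsule'); the predicate
    ('eat' -> take) decides."""
    schema = default_schema()
    g = PatientGraph(schema, DataGraph(nodes={
        "p1": Node("p1", "patient 1", "patient", {"sex": "female", "age": 40}),
        "d1": Node("d1", "cold", "disease"),
        "r1": Node("r1", "Coldrine capsule", "drug"),
    }))
    lex = Lexicon([
        LexiconEntry("take", "take", ConceptType.RELATION, ("eat", "took")),
        LexiconEntry("count", "count", ConceptType.STATISTIC_OPERATOR),
        LexiconEntry("patients", "patient", ConceptType.CLASS),
        LexiconEntry("cold", "d1", ConceptType.INSTANCE, (), "disease"),
        LexiconEntry("Coldrine capsule", "r1", ConceptType.INSTANCE, (), "drug"),
    ])
    cfg = __import__("cohortqa").PipelineConfig(sim_floor=0.3)
    return Pipeline(g, lex, cfg)


def test_predicate_range_disambiguates_coldrine():
    pipe = _coldrine_pipeline()
    tree, answer = pipe.interpret("eat Coldrine patients count")
    assert answer.covered
    assert serialize(tree) == "<patient, take, Coldrine capsule> <patient, count, ?>"


def test_single_candidate_is_returned_unchanged():
    schema = default_schema()
    t = SemanticTree([AttrTriple("patient", "sex", EnumV("female"))],
                     QuerySpec("count"))
    assert disambiguate([t], schema) is t


def test_higher_sigma_candidate_wins_between_schema_valid_readings():
    schema = default_schema()
    a = SemanticTree([EventTriple("patient", "suffer", "hyperglycemia", "disease",
                                  "d0", sigma=1.0)], QuerySpec("count"))
    b = SemanticTree([EventTriple("patient", "suffer", "hypertension", "disease",
                                  "d1", sigma=0.6)], QuerySpec("count"))
    a.sigma, b.sigma = 1.0, 0.6
    assert disambiguate([b, a], schema) is a
    # pure function: repeated calls agree
    assert disambiguate([b, a], schema) is disambiguate([a, b], schema)


def test_empty_candidate_set_is_unanswerable():
    with pytest.raises(UnanswerableError):
        disambiguate([], default_schema())


# ---------------------------------------------------------------------------
# time attachment
# ---------------------------------------------------------------------------

def _suffer(label="hyperglycemia", negated=False):
    return EventTriple("patient", "suffer", label, "disease", "d0", negated=negated)


def _take(label="hypoglycemic drugs"):
    return EventTriple("patient", "take", label, "drug", "r0")


def test_explicit_join_absorbs_preceding_diagnoses():
    schema = default_schema()
    tree = SemanticTree([
        _suffer(), _suffer("hypertension", negated=True),
        TimeJoin("after", _take(), _suffer("diabetes")),
    ], QuerySpec("count"))
    out = attach_time(tree, schema)
    assert len(out.conditions) == 1
    assert serialize(out).startswith(
        "(<patient, suffer, hyperglycemia> (not <patient, suffer, hypertension>)) "
        "after <patient, take, hypoglycemic drugs> after")


def test_no_time_operator_means_no_time_join():
    schema = default_schema()
    tree = SemanticTree([_suffer(), _take()], QuerySpec("count"))
    out = attach_time(tree, schema)
    assert not any(isinstance(c, TimeJoin) for c in out.conditions)


def test_attribute_conditions_are_not_absorbed():
    schema = default_schema()
    tree = SemanticTree([
        AttrTriple("patient", "sex", EnumV("female")),
        TimeJoin("after", _take(), _suffer()),
    ], QuerySpec("count"))
    out = attach_time(tree, schema)
    assert len(out.conditions) == 2
    assert isinstance(out.conditions[0], AttrTriple)


def test_higher_rank_conditions_are_not_absorbed():
    schema = default_schema()
    test_triple = EventTriple("patient", "have test", "blood glucose", "test", "t0")
    tree = SemanticTree([test_triple, TimeJoin("after", _suffer(), _take())],
                        QuerySpec("count"))
    out = attach_time(tree, schema)
    assert len(out.conditions) == 2  # tests rank after diagnoses: no absorption
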