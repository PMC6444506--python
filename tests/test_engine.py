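import numpy as np
import pytest

from cohortqa import (AttrTriple, Cmp, EnumV, EventTriple, GeneratorConfig, Group,
                      QuerySpec, ResultSet, SemanticTree, StatisticTypeError,
                      TimeFilter, TimeJoin, compute_statistic, execute,
                      generate_graph, node_by_label, oracle_execute, random_tree,
                      results_equal, serialize, to_cypher)
from cohortqa.kg_store import DataGraph, Edge, Node, PatientGraph, default_schema


@pytest.fixture(scope="module")
def small():
    return generate_graph(GeneratorConfig(n_patients=40, seed=21))


def _suffer(g, label, **kw):
    n = node_by_label(g, label)
    return EventTriple("patient", "suffer", n.label, "disease", n.id, **kw)


def _take(g, label, **kw):
    n = node_by_label(g, label)
    return EventTriple("patient", "take", n.label, "drug", n.id, **kw)


# ---------------------------------------------------------------------------
# executor semantics
# ---------------------------------------------------------------------------

def test_empty_condition_count_is_total_patients(small):
    tree = SemanticTree([], QuerySpec("count"))
    assert execute(tree, small).payload == len(small.patients())


def test_complement_law(small):
    for label in ("hyperglycemia", "diabetes", "disease 00"):
        pos = SemanticTree([_suffer(small, label)], QuerySpec("count"))
        neg = SemanticTree([_suffer(small, label, negated=True)], QuerySpec("count"))
        assert execute(pos, small).payload + execute(neg, small).payload == \
            len(small.patients())


def test_monotonicity_laws(small):
    a = _suffer(small, "hyperglycemia")
    b = _take(small, "aspirin")
    ca = execute(SemanticTree([a], QuerySpec("count")), small).payload
    cb = execute(SemanticTree([b], QuerySpec("count")), small).payload
    c_and = execute(SemanticTree([Group("and", [a, b])], QuerySpec("count")),
                    small).payload
    c_or = execute(SemanticTree([Group("or", [a, b])], QuerySpec("count")),
                   small).payload
    assert c_and <= min(ca, cb)
    assert c_or >= max(ca, cb)
    assert c_and + c_or == ca + cb


def test_planted_chronology_count():
    """Exactly 3 of the planted patients have diagnose < take < low test."""
    from cohortqa import fixture_graph
    g = fixture_graph()
    chain = TimeJoin(
        "after",
        TimeJoin("after", _suffer(g, "hyperglycemia"), _take(g, "hypoglycemic drugs")),
        EventTriple("patient", "have test", "blood glucose", "test",
                    node_by_label(g, "blood glucose").id,
                    constraint=__import__("cohortqa").AttrConstraint(
                        "test result", EnumV("low"))))
    planted = set(sorted(n.id for n in g.patients())[:4])
    from cohortqa.engine import cohort_of
    cohort, _ = cohort_of(SemanticTree([chain], QuerySpec("count")), g)
    assert cohort & planted == set(sorted(planted)[:3])


def test_same_day_events_satisfy_neither_direction():
    schema = default_schema()
    g = PatientGraph(schema, DataGraph(
        nodes={"p1": Node("p1", "x", "patient"),
               "d1": Node("d1", "flu", "disease"),
               "r1": Node("r1", "aspirin", "drug")},
        edges=[Edge("p1", "suffer", "d1", 20150610),
               Edge("p1", "take", "r1", 20150610)]))
    for left_earlier in (True, False):
        tree = SemanticTree([TimeJoin(
            "after",
            EventTriple("patient", "suffer", "flu", "disease", "d1"),
            EventTriple("patient", "take", "aspirin", "drug", "r1"),
            left_earlier)], QuerySpec("count"))
        assert execute(tree, g).payload == 0


def test_missing_timestamp_excluded_from_time_joins():
    schema = default_schema()
    g = PatientGraph(schema, DataGraph(
        nodes={"p1": Node("p1", "x", "patient"),
               "d1": Node("d1", "flu", "disease"),
               "r1": Node("r1", "aspirin", "drug")},
        edges=[Edge("p1", "suffer", "d1", None),
               Edge("p1", "take", "r1", 20150610)]))
    tree = SemanticTree([TimeJoin(
        "after", EventTriple("patient", "suffer", "flu", "disease", "d1"),
        EventTriple("patient", "take", "aspirin", "drug", "r1"))], QuerySpec("count"))
    assert execute(tree, g).payload == 0
    # but the un-timed triple alone still matches
    plain = SemanticTree([EventTriple("patient", "suffer", "flu", "disease", "d1")],
                         QuerySpec("count"))
    assert execute(plain, g).payload == 1


def test_time_filter_on_edge(small):
    unfiltered = execute(SemanticTree([_take(small, "aspirin")],
                                      QuerySpec("count")), small).payload
    filtered = execute(SemanticTree(
        [_take(small, "aspirin", time_filter=TimeFilter(20140101, 20141231))],
        QuerySpec("count")), small).payload
    assert 0 <= filtered <= unfiltered


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _attr_graph():
    schema = default_schema()
    nodes = {}
    ages = {"p1": 60, "p2": 70, "p3": 80}
    sexes = {"p1": "female", "p2": "female", "p3": "male"}
    for pid in ages:
        nodes[pid] = Node(pid, pid, "patient",
                          {"age": ages[pid], "sex": sexes[pid]})
    nodes["p4"] = Node("p4", "p4", "patient", {"sex": "female"})  # age missing
    nodes["p5"] = Node("p5", "p5", "patient", {"sex": "male", "age": 50})
    return PatientGraph(schema, DataGraph(nodes=nodes))


def test_average_age_arithmetic():
    g = _attr_graph()
    cohort = {"p1", "p2", "p3"}
    r = compute_statistic(cohort, QuerySpec("avg", "property", "age"), g)
    assert r.payload == pytest.approx(70.0)
    assert r.excluded == 0


def test_missing_attribute_excluded_with_report():
    g = _attr_graph()
    cohort = {"p1", "p2", "p3", "p4"}
    r = compute_statistic(cohort, QuerySpec("avg", "property", "age"), g)
    assert r.payload == pytest.approx(70.0)
    assert r.excluded == 1


def test_avg_on_non_numeric_property_is_a_type_error():
    g = _attr_graph()
    with pytest.raises(StatisticTypeError):
        compute_statistic({"p1"}, QuerySpec("avg", "property", "sex"), g)


def test_distribution_mass_conservation():
    g = _attr_graph()
    cohort = {"p1", "p2", "p3", "p5"}
    r = compute_statistic(cohort, QuerySpec("distribution", "property", "sex"), g)
    assert r.payload == {"female": 2, "male": 2}
    assert sum(r.payload.values()) == len(cohort)


def test_age_distribution_uses_width_10_bins_anchored_at_zero():
    g = _attr_graph()
    r = compute_statistic({"p1", "p2", "p3", "p5"},
                          QuerySpec("distribution", "property", "age"), g)
    assert r.payload == {"[50, 60)": 1, "[60, 70)": 1, "[70, 80)": 1, "[80, 90)": 1}


def test_ratio_bounds_and_undefined_cases(small):
    hyper = _suffer(small, "hyperglycemia")
    tree = SemanticTree([hyper, _take(small, "aspirin")], QuerySpec("ratio"),
                        numerator_index=1)
    r = execute(tree, small)
    assert r.type == "ratio" and 0.0 <= r.payload <= 1.0
    # numerator condition implied by the cohort -> ratio 1.0
    tree2 = SemanticTree([hyper, _suffer(small, "hyperglycemia")],
                         QuerySpec("ratio"), numerator_index=1)
    assert execute(tree2, small).payload == 1.0
    # empty cohort -> undefined, not zero
    impossible = AttrTriple("patient", "age", Cmp("gt", 1000.0))
    tree3 = SemanticTree([impossible, hyper], QuerySpec("ratio"), numerator_index=1)
    r3 = execute(tree3, small)
    assert r3.undefined and r3.payload is None


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def test_oracle_on_trivial_graphs():
    schema = default_schema()
    empty = PatientGraph(schema)
    tree = SemanticTree([], QuerySpec("count"))
    assert oracle_execute(tree, empty).payload == 0
    single = PatientGraph(schema, DataGraph(
        nodes={"p1": Node("p1", "patient one", "patient", {"sex": "female"})}))
    listed = oracle_execute(
        SemanticTree([AttrTriple("patient", "sex", EnumV("female"))],
                     QuerySpec("list")), single)
    assert listed.payload == [{"id": "p1", "label": "patient one"}]


def test_executor_equals_oracle_on_random_cases():
    rng = np.random.default_rng(2024)
    g = None
    for i in range(200):
        if i % 50 == 0:
            g = generate_graph(GeneratorConfig(n_patients=30, seed=300 + i))
        tree = random_tree(g, rng)
        a, b = execute(tree, g), oracle_execute(tree, g)
        assert results_equal(a, b), serialize(tree)


# ---------------------------------------------------------------------------
# Cypher translation
# ---------------------------------------------------------------------------

def test_negated_triple_becomes_where_not_pattern(small):
    tree = SemanticTree([_suffer(small, "hyperglycemia"),
                         _suffer(small, "hypertension", negated=True)],
                        QuerySpec("count"))
    text = to_cypher(tree, small.schema)
    assert "NOT (p)-[:`suffer`]->(:`disease` {name: 'hypertension'})" in text
    assert "{name: 'hypertension'}" not in text.split("\n")[0]  # not in MATCH


def test_time_join_becomes_timestamp_inequality(small):
    tree = SemanticTree(
        [TimeJoin("after", _take(small, "hypoglycemic drugs"),
                  _suffer(small, "diabetes"))], QuerySpec("count"))
    text = to_cypher(tree, small.schema)
    assert "r1.timestamp < r2.timestamp" in text


def test_count_query_returns_patient_count_aggregate(small):
    tree = SemanticTree([_suffer(small, "diabetes")], QuerySpec("count"))
    assert to_cypher(tree, small.schema).endswith(
        "RETURN count(DISTINCT p) AS value")


def test_cypher_is_deterministic_golden(small):
    tree = SemanticTree(
        [_suffer(small, "hyperglycemia"),
         AttrTriple("patient", "sex", EnumV("female"))],
        QuerySpec("count"))
    expected = (
        "MATCH (p:`patient`), "
        "(p)-[r1:`suffer`]->(n1:`disease` {name: 'hyperglycemia'})\n"
        "WHERE (p.`sex` = 'female')\n"
        "RETURN count(DISTINCT p) AS value")
    assert to_cypher(tree, small.schema) == expected
    assert to_cypher(tree, small.schema) == expected  # byte-identical again
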