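"""Synthetic patient graphs, fixture lexicons and gold-standard questions.

The generator emulates the shape of a heart-failure clinical data
repository converted to a property graph: a patient class plus five
event classes (disease, drug, test, procedure, hospitalization) linked
by time-stamped edges, with drug exposures the most frequent event type,
followed by tests, then diagnoses/procedures/admissions.  The default
scale (100 patients, on the order of 2,000 edges) keeps every test in
the seconds range; all sampling is driven by one seed and is
byte-identical across runs.

Question templates mirror the families doctors actually ask about such
repositories (demographics, drug usage, etiology, comparative
effectiveness).  Template text follows the head-final word order of the
source questions ("with hyperglycemia patients count"), which keeps the
Latin-script fixtures aligned with the grammar; gold answers are
computed with the brute-force oracle, never with the engine under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .engine import ResultSet, oracle_execute
from .kg_store import Edge, Node, PatientGraph, default_schema
from .segmentation import Lexicon, core_lexicon, lexicon_from_graph, zh_label_map
from .semantics import (AttrTriple, Cmp, EnumV, EventTriple, Group, NumRange,
                        QuerySpec, SemanticTree, TimeFilter, TimeJoin)

NAMED_DISEASES = ("hyperglycemia", "hypertension", "diabetes",
                  "heart failure", "coronary heart disease")
NAMED_DRUGS = ("hypoglycemic drugs", "glucose oral liquid", "captopril",
               "aspirin", "metformin")
NAMED_TESTS = ("blood glucose", "blood pressure")
NAMED_PROCEDURES = ("stent implant",)


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    n_diseases: int = 12
    n_drugs: int = 15
    n_tests: int = 8
    n_procedures: int = 6
    #: mean event counts per patient (Poisson), ordered like the source
    #: repository: drug exposures dominate, then tests, then the rest
    mean_diagnose: float = 2.7
    mean_take: float = 6.0
    mean_test: float = 4.0
    mean_operate: float = 1.0
    mean_admit: float = 1.5
    year_lo: int = 2012
    year_hi: int = 2017
    seed: int = 0

    def validate(self) -> None:
        counts = {"n_patients": self.n_patients, "n_diseases": self.n_diseases,
                  "n_drugs": self.n_drugs, "n_tests": self.n_tests,
                  "n_procedures": self.n_procedures}
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for named, n, what in ((NAMED_DISEASES, self.n_diseases, "diseases"),
                               (NAMED_DRUGS, self.n_drugs, "drugs"),
                               (NAMED_TESTS, self.n_tests, "tests"),
                               (NAMED_PROCEDURES, self.n_procedures, "procedures")):
            if n < len(named):
                raise ValueError(
                    f"catalog of {what} cannot hold the {len(named)} named entities")


def _catalog(named: Sequence[str], n: int, stem: str) -> list[str]:
    fillers = [f"{stem} {i:02d}" for i in range(n - len(named))]
    return list(named) + fillers


def _random_date(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    y = int(rng.integers(cfg.year_lo, cfg.year_hi + 1))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    return y * 10000 + m * 100 + d


def generate_graph(cfg: GeneratorConfig = GeneratorConfig()) -> PatientGraph:
    """A schema-conformant random patient graph (seeded, deterministic)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g = PatientGraph(default_schema())

    catalogs = {
        "disease": _catalog(NAMED_DISEASES, cfg.n_diseases, "disease"),
        "drug": _catalog(NAMED_DRUGS, cfg.n_drugs, "drug"),
        "test": _catalog(NAMED_TESTS, cfg.n_tests, "test"),
        "procedure": _catalog(NAMED_PROCEDURES, cfg.n_procedures, "procedure"),
    }
    prefix = {"disease": "d", "drug": "r", "test": "t", "procedure": "o"}
    ids: dict[str, list[str]] = {}
    for cls, labels in catalogs.items():
        ids[cls] = []
        for i, label in enumerate(labels):
            nid = f"{prefix[cls]}{i:03d}"
            g.data.nodes[nid] = Node(nid, label, cls)
            ids[cls].append(nid)

    hosp_counter = 0
    for i in range(cfg.n_patients):
        pid = f"p{i:04d}"
        sex = "female" if rng.random() < 0.5 else "male"
        age = int(rng.integers(18, 91))
        birthday = (2017 - age) * 10000 + int(rng.integers(1, 13)) * 100 \
            + int(rng.integers(1, 29))
        g.data.nodes[pid] = Node(pid, f"patient {i:04d}", "patient",
                                 {"sex": sex, "age": age, "birthday": birthday})
        for _ in range(int(rng.poisson(cfg.mean_diagnose))):
            g.data.edges.append(Edge(pid, "suffer",
                                     str(rng.choice(ids["disease"])),
                                     _random_date(rng, cfg)))
        for _ in range(int(rng.poisson(cfg.mean_take))):
            g.data.edges.append(Edge(pid, "take", str(rng.choice(ids["drug"])),
                                     _random_date(rng, cfg)))
        for _ in range(int(rng.poisson(cfg.mean_test))):
            v = round(float(np.clip(rng.normal(5.5, 2.0), 0.1, None)), 2)
            flag = "low" if v < 4.0 else ("high" if v > 7.0 else "normal")
            g.data.edges.append(Edge(pid, "have test", str(rng.choice(ids["test"])),
                                     _random_date(rng, cfg), value=v, result=flag))
        for _ in range(int(rng.poisson(cfg.mean_operate))):
            g.data.edges.append(Edge(pid, "operate",
                                     str(rng.choice(ids["procedure"])),
                                     _random_date(rng, cfg)))
        for _ in range(int(rng.poisson(cfg.mean_admit))):
            hid = f"h{hosp_counter:05d}"
            hosp_counter += 1
            g.data.nodes[hid] = Node(hid, "hospitalization", "hospitalization")
            g.data.edges.append(Edge(pid, "in hospital", hid,
                                     _random_date(rng, cfg),
                                     value=float(1 + rng.poisson(5))))
    g.validate()
    return g


def node_by_label(g: PatientGraph, label: str) -> Node:
    for n in g.data.nodes.values():
        if n.label == label:
            return n
    raise KeyError(label)


def fixture_graph(seed: int = 0, n_patients: int = 30) -> PatientGraph:
    """A small graph on which the bundled worked examples are satisfiable.

    Three patients are deterministically planted to match the canonical
    question (female, hyperglycemia but no hypertension, hypoglycemic
    drugs taken after the diagnosis, low blood-glucose test after the
    drugs); one near-miss patient violates only the chronology.
    """
    cfg = GeneratorConfig(n_patients=n_patients, seed=seed)
    g = generate_graph(cfg)
    hyper = node_by_label(g, "hyperglycemia").id
    ht = node_by_label(g, "hypertension").id
    drug = node_by_label(g, "hypoglycemic drugs").id
    bg = node_by_label(g, "blood glucose").id
    planted = sorted(n.id for n in g.patients())[:4]
    control = {hyper, ht, drug, bg}
    for pid in planted:
        # the planted patients' history of the canonical entities is exact
        g.data.edges = [e for e in g.data.edges
                        if not (e.source == pid and e.target in control)]
        g.data.nodes[pid].attrs["sex"] = "female"
    for pid in planted[:3]:
        g.data.edges.extend([
            Edge(pid, "suffer", hyper, 20130105),
            Edge(pid, "take", drug, 20140210),
            Edge(pid, "have test", bg, 20150315, value=3.2, result="low"),
        ])
    # near miss: same events, but the low test precedes the drug exposure
    g.data.edges.extend([
        Edge(planted[3], "suffer", hyper, 20130105),
        Edge(planted[3], "take", drug, 20150210),
        Edge(planted[3], "have test", bg, 20140315, value=3.2, result="low"),
    ])
    g.validate()
    return g


def fixture_lexicon(g: PatientGraph, script: str = "en") -> Lexicon:
    """The question lexicon for a generated graph ('en' or 'zh')."""
    label_map = zh_label_map() if script == "zh" else None
    return lexicon_from_graph(g, core_lexicon(script), label_map=label_map)


# ---------------------------------------------------------------------------
# question templates with oracle-computed gold answers
# ---------------------------------------------------------------------------

def _suffer(g, label, negated=False, tf=None):
    n = node_by_label(g, label)
    return EventTriple("patient", "suffer", n.label, "disease", n.id,
                       negated=negated, time_filter=tf)


def _take(g, label, tf=None):
    n = node_by_label(g, label)
    return EventTriple("patient", "take", n.label, "drug", n.id, time_filter=tf)


@dataclass(frozen=True)
class QuestionTemplate:
    tid: str
    pattern: str
    slots: tuple[str, ...]  # slot kinds: 'disease' | 'drug' | 'age' | 'sex' | 'dates'
    build: Callable


def _t(tid, pattern, slots, build):
    return QuestionTemplate(tid, pattern, slots, build)


DEFAULT_TEMPLATES: tuple[QuestionTemplate, ...] = (
    _t("count", "with {0} patients count", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0])], QuerySpec("count"))),
    _t("negation", "no with {0} patients count", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0], negated=True)], QuerySpec("count"))),
    _t("coordination", "with {0} and {1} patients count", ("disease", "disease"),
       lambda g, e: SemanticTree([_suffer(g, e[0]), _suffer(g, e[1])],
                                 QuerySpec("count"))),
    _t("disjunction", "with {0} or with {1} patients count", ("disease", "disease"),
       lambda g, e: SemanticTree([Group("or", [_suffer(g, e[0]), _suffer(g, e[1])])],
                                 QuerySpec("count"))),
    _t("drug", "took {0} patients count", ("drug",),
       lambda g, e: SemanticTree([_take(g, e[0])], QuerySpec("count"))),
    _t("comorbidity", "with {0} and took {1} patients count", ("disease", "drug"),
       lambda g, e: SemanticTree([_suffer(g, e[0]), _take(g, e[1])],
                                 QuerySpec("count"))),
    _t("chronology", "with {0} after took {1} patients count", ("disease", "drug"),
       lambda g, e: SemanticTree(
           [TimeJoin("after", _suffer(g, e[0]), _take(g, e[1]))], QuerySpec("count"))),
    _t("average", "with {0} patients age average", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0])],
                                 QuerySpec("avg", "property", "age"))),
    _t("total", "with {0} patients age sum", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0])],
                                 QuerySpec("sum", "property", "age"))),
    _t("distribution", "with {0} patients sex distribution", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0])],
                                 QuerySpec("distribution", "property", "sex"))),
    _t("listing", "with {0} patients list", ("disease",),
       lambda g, e: SemanticTree([_suffer(g, e[0])], QuerySpec("list"))),
    _t("ratio", "with {0} patients with {1} ratio", ("disease", "disease"),
       lambda g, e: SemanticTree([_suffer(g, e[0]), _suffer(g, e[1])],
                                 QuerySpec("ratio"), numerator_index=1)),
    _t("age-threshold", "age over {0} years old patients count", ("age",),
       lambda g, e: SemanticTree([AttrTriple("patient", "age", Cmp("gt", float(e[0])))],
                                 QuerySpec("count"))),
    _t("demographic", "{0} patients count", ("sex",),
       lambda g, e: SemanticTree([AttrTriple("patient", "sex", EnumV(e[0]))],
                                 QuerySpec("count"))),
    _t("period", "{0} to {1} took {2} patients count", ("dates", "dates", "drug"),
       lambda g, e: SemanticTree(
           [_take(g, e[2], tf=TimeFilter(int(e[0]), int(e[1])))], QuerySpec("count"))),
)


@dataclass
class GeneratedQuestion:
    text: str
    tree: SemanticTree
    gold: ResultSet
    template: str


def generate_questions(g: PatientGraph, n: int = 50, seed: int = 0,
                       templates: Sequence[QuestionTemplate] = DEFAULT_TEMPLATES,
                       cfg: PipelineConfig = DEFAULT_CONFIG) -> list[GeneratedQuestion]:
    """Instantiate templates with entities from the graph; gold answers come
    from the brute-force oracle."""
    rng = np.random.default_rng(seed)
    diseases = sorted(n_.label for n_ in g.nodes_of_class("disease"))
    drugs = sorted(n_.label for n_ in g.nodes_of_class("drug"))
    out: list[GeneratedQuestion] = []
    for i in range(n):
        tpl = templates[int(rng.integers(len(templates)))]
        ents: list[str] = []
        for kind in tpl.slots:
            if kind == "disease":
                pool = [d for d in diseases if d not in ents]
                ents.append(str(rng.choice(pool)))
            elif kind == "drug":
                pool = [d for d in drugs if d not in ents]
                ents.append(str(rng.choice(pool)))
            elif kind == "age":
                ents.append(str(int(rng.integers(30, 80))))
            elif kind == "sex":
                ents.append("female" if rng.random() < 0.5 else "male")
            elif kind == "dates":
                ents.append(str(_random_date(rng, GeneratorConfig())))
            else:
                raise ValueError(f"unknown slot kind {kind!r}")
        if "dates" in tpl.slots:
            lo, hi = sorted(int(x) for x in ents[:2])
            ents[0], ents[1] = str(lo), str(hi)
        text = tpl.pattern.format(*ents)
        tree = tpl.build(g, ents)
        gold = oracle_execute(tree, g, cfg)
        out.append(GeneratedQuestion(text, tree, gold, tpl.tid))
    return out


# ---------------------------------------------------------------------------
# random semantic trees (executor-vs-oracle property tests)
# ---------------------------------------------------------------------------

def random_tree(g: PatientGraph, rng: np.random.Generator,
                max_conditions: int = 3) -> SemanticTree:
    """A random schema-valid semantic tree over the graph's catalogs."""
    diseases = sorted(n.label for n in g.nodes_of_class("disease"))
    drugs = sorted(n.label for n in g.nodes_of_class("drug"))

    def event() -> EventTriple:
        if rng.random() < 0.5:
            t = _suffer(g, str(rng.choice(diseases)))
        else:
            t = _take(g, str(rng.choice(drugs)))
        if rng.random() < 0.25:
            t.negated = True
        elif rng.random() < 0.2:
            t.time_filter = TimeFilter(20130101, 20151231)
        return t

    def attr() -> AttrTriple:
        if rng.random() < 0.5:
            return AttrTriple("patient", "sex",
                              EnumV("female" if rng.random() < 0.5 else "male"),
                              negated=rng.random() < 0.3)
        lo = int(rng.integers(20, 60))
        value = Cmp("gt", float(lo)) if rng.random() < 0.5 \
            else NumRange(float(lo), float(lo + 20))
        return AttrTriple("patient", "age", value)

    def element():
        u = rng.random()
        if u < 0.35:
            return event()
        if u < 0.5:
            return attr()
        if u < 0.8:
            op = "and" if rng.random() < 0.5 else "or"
            return Group(op, [event(), event() if rng.random() < 0.7 else attr()])
        left = EventTriple(**{**event().__dict__, "negated": False})
        right = EventTriple(**{**event().__dict__, "negated": False})
        join = TimeJoin("after" if rng.random() < 0.7 else "before", left, right,
                        left_earlier=rng.random() < 0.7)
        if rng.random() < 0.3:  # chain of three events
            third = EventTriple(**{**event().__dict__, "negated": False})
            join = TimeJoin(join.word, join, third, join.left_earlier)
        return join

    conditions = [element() for _ in range(int(rng.integers(0, max_conditions + 1)))]
    stat = str(rng.choice(["count", "count", "list", "avg", "sum",
                           "distribution", "distribution", "ratio"]))
    if stat in ("avg", "sum"):
        query = QuerySpec(stat, "property", "age")
    elif stat == "distribution":
        query = QuerySpec(stat, "property",
                          "sex" if rng.random() < 0.5 else "age")
    else:
        query = QuerySpec(stat)
    tree = SemanticTree(conditions, query)
    if stat == "ratio":
        positive = event()
        positive.negated = False
        tree.conditions.append(positive)
        tree.numerator_index = len(tree.conditions) - 1
    return tree
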