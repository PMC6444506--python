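"""Tree-like knowledge representation of analytic questions.

A question becomes a set of *triples* joined by logical and time
operators plus exactly one query item (the statistic and its target).
Operator precedence: Not binds tightest (it always wraps a single
triple), logical operators next, time operators loosest; grouping is
shown with parentheses in the canonical serialization.

Entity and predicate ambiguity surviving the parse is resolved here
against the patient-schema graph: candidate readings whose triples have
no (domain, predicate, range) support are dropped, and the survivor with
the most schema-realizable triples (then the highest summed linking
similarity) wins.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union

from .concepts import STATISTICS
from .config import DEFAULT_CONFIG, PipelineConfig
from .grammar import ParseForest, ParseTree
from .kg_store import SchemaGraph
from .linking import TypedSequence


class UnanswerableError(ValueError):
    """No schema-compatible reading of the question exists."""


# ---------------------------------------------------------------------------
# values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnumV:
    value: str

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class NumV:
    value: float

    def __str__(self) -> str:
        return f"{self.value:g}"


@dataclass(frozen=True)
class Cmp:
    op: str  # 'gt' | 'lt' | 'ge' | 'le' | 'eq'
    value: float

    _WORDS = {"gt": "over", "lt": "under", "ge": "at least", "le": "at most", "eq": "="}

    def __str__(self) -> str:
        word = self._WORDS[self.op]
        return f"{NumV(self.value)}" if self.op == "eq" else f"{word} {NumV(self.value)}"


@dataclass(frozen=True)
class NumRange:
    lo: float
    hi: float

    def __str__(self) -> str:
        return f"{NumV(self.lo)}-{NumV(self.hi)}"


@dataclass(frozen=True)
class TimeFilter:
    """Inclusive yyyymmdd bounds on an event edge; None = open end."""
    lo: Optional[int] = None
    hi: Optional[int] = None

    def __str__(self) -> str:
        if self.lo is not None and self.lo == self.hi:
            return str(self.lo)
        return f"{self.lo or ''}-{self.hi or ''}"

    def contains(self, ts: int) -> bool:
        return (self.lo is None or ts >= self.lo) and (self.hi is None or ts <= self.hi)


Value = Union[EnumV, NumV, Cmp, NumRange, TimeFilter]


@dataclass(frozen=True)
class AttrConstraint:
    """A constraint on an attribute carried by the event edge itself."""
    attribute: str
    value: Value


# ---------------------------------------------------------------------------
# condition elements
# ---------------------------------------------------------------------------

@dataclass
class EventTriple:
    """<subject class, event predicate, instance-or-class> with filters."""

    subject: str
    predicate: str
    object_label: str
    object_cls: str
    object_id: Optional[str] = None  # None = any instance of object_cls
    negated: bool = False
    constraint: Optional[AttrConstraint] = None
    time_filter: Optional[TimeFilter] = None
    sigma: float = 0.0

    def parts(self) -> list[tuple[str, str, str]]:
        out = [(self.subject, self.predicate, self.object_label)]
        if self.constraint is not None:
            out.append((self.object_label, self.constraint.attribute,
                        str(self.constraint.value)))
        return out


@dataclass
class AttrTriple:
    """<subject class, attribute, value> on the subject node."""

    subject: str
    attribute: str
    value: Value
    negated: bool = False
    sigma: float = 0.0

    def parts(self) -> list[tuple[str, str, str]]:
        return [(self.subject, self.attribute, str(self.value))]


@dataclass
class GenericTriple:
    """A structure-only triple (used by the serialization parser)."""

    s: str
    p: str
    o: str
    negated: bool = False
    suffix: str = ""
    sigma: float = 0.0
    constraint: None = None
    time_filter: None = None

    def parts(self) -> list[tuple[str, str, str]]:
        return [(self.s, self.p, self.o)]


@dataclass
class Group:
    op: str  # 'and' | 'or'
    children: list = field(default_factory=list)


@dataclass
class TimeJoin:
    """Chronological join; by convention the left subtree's events are
    the earlier ones when the operator word is "after" (sequencing
    reading: "A after B" = A, and afterwards B)."""

    word: str
    left: object
    right: object
    left_earlier: bool = True


Condition = Union[EventTriple, AttrTriple, GenericTriple, Group, TimeJoin]


@dataclass
class QuerySpec:
    statistic: str
    target_kind: str = "cohort"  # 'cohort' | 'property' | 'related' | 'instance_property'
    target: Optional[str] = None  # property or class name
    relation: Optional[str] = None  # for 'related'
    instance_label: Optional[str] = None  # for 'instance_property'
    instance_id: Optional[str] = None
    instance_cls: Optional[str] = None

    def part(self, subject: str) -> tuple[str, str, str]:
        if self.target_kind == "instance_property":
            return (self.instance_label, self.target, self.statistic)
        return (subject, self.statistic, self.target or "?")


@dataclass
class SemanticTree:
    conditions: list = field(default_factory=list)  # adjacency = And
    query: QuerySpec = field(default_factory=lambda: QuerySpec("count"))
    subject_class: str = "patient"
    numerator_index: Optional[int] = None  # ratio numerator position
    sigma: float = 0.0


# ---------------------------------------------------------------------------
# canonical serialization
# ---------------------------------------------------------------------------

def _ser_element(el, wrap_time: bool = False) -> str:
    if isinstance(el, (EventTriple, AttrTriple, GenericTriple)):
        parts = el.parts()
        texts = [f"<{s}, {p}, {o}>" for s, p, o in parts]
        if getattr(el, "time_filter", None) is not None:
            texts[0] += f"@{el.time_filter}"
        if isinstance(el, GenericTriple) and el.suffix:
            texts[0] += el.suffix
        body = " ".join(texts)
        if el.negated:
            return f"(not {body})"
        return f"({body})" if len(texts) > 1 else body
    if isinstance(el, Group):
        sep = " " if el.op == "and" else " or "
        return "(" + sep.join(_ser_element(c, wrap_time=True) for c in el.children) + ")"
    if isinstance(el, TimeJoin):
        body = f"{_ser_element(el.left)} {el.word} {_ser_element(el.right)}"
        return f"({body})" if wrap_time else body
    raise TypeError(f"cannot serialize {el!r}")


def serialize(tree: SemanticTree) -> str:
    """Deterministic canonical text form; adjacency denotes And."""
    chunks = [_ser_element(c) for c in tree.conditions]
    s, p, o = tree.query.part(tree.subject_class)
    chunks.append(f"<{s}, {p}, {o}>")
    return " ".join(chunks)


_TOKEN_RE = re.compile(r"<([^<>]+)>(@[0-9\-]+)?|\(|\)|[^\s()<>]+")


def parse_serialized(text: str) -> SemanticTree:
    """Parse the canonical text form back into a (structure-level) tree."""
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        if m.group(1) is not None:
            tokens.append(("triple", m.group(1), m.group(2) or ""))
        else:
            tokens.append((m.group(0),))
    pos = 0

    def parse_level(stop_at_paren: bool):
        nonlocal pos
        items: list = []
        seps: list[str] = []
        negated = False
        while pos < len(tokens):
            tok = tokens[pos]
            if tok[0] == ")":
                if not stop_at_paren:
                    raise ValueError("unbalanced ')'")
                pos += 1
                break
            if tok[0] == "(":
                pos += 1
                items.append(parse_level(True))
            elif tok[0] == "triple":
                pos += 1
                s, p, o = (part.strip() for part in tok[1].split(",", 2))
                items.append(GenericTriple(s, p, o, suffix=tok[2]))
            elif tok[0] == "not":
                pos += 1
                negated = True
            else:  # operator word: 'or' or a time word
                seps.append(tok[0])
                items.append(None)  # separator marker
                pos += 1
        # fold time words (bind the two adjacent items, left-associative)
        folded: list = []
        si = 0
        i = 0
        while i < len(items):
            if items[i] is None:
                word = seps[si]
                si += 1
                if word != "or":
                    left = folded.pop()
                    right = items[i + 1]
                    folded.append(TimeJoin(word, left, right))
                    i += 2
                    continue
                folded.append("or")
            else:
                folded.append(items[i])
            i += 1
        if "or" in folded:
            children = [x for x in folded if x != "or"]
            result: object = Group("or", children)
        elif len(folded) == 1:
            result = folded[0]
        else:
            result = Group("and", list(folded)) if stop_at_paren else folded
        if negated:
            if isinstance(result, GenericTriple):
                result = replace(result, negated=True)
            else:
                raise ValueError("'not' must wrap exactly one triple")
        return result

    top = parse_level(False)
    elements = top if isinstance(top, list) else [top]
    if not elements or not isinstance(elements[-1], GenericTriple):
        raise ValueError("missing query item")
    q = elements.pop()
    if q.p in STATISTICS:
        kind = "cohort" if q.o == "?" else "property"
        query = QuerySpec(q.p, kind, None if q.o == "?" else q.o)
        subject = q.s
    elif q.o in STATISTICS:
        query = QuerySpec(q.o, "instance_property", q.p, instance_label=q.s)
        subject = "patient"
    else:
        raise ValueError(f"last triple {q} is not a query item")
    return SemanticTree(conditions=elements, query=query, subject_class=subject)


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def _walk_parts(el) -> tuple[list[tuple[str, str, str]], int]:
    if isinstance(el, (EventTriple, AttrTriple, GenericTriple)):
        return el.parts(), 0
    if isinstance(el, Group):
        parts, joins = [], 0
        for c in el.children:
            p, j = _walk_parts(c)
            parts.extend(p)
            joins += j
        return parts, joins
    if isinstance(el, TimeJoin):
        lp, lj = _walk_parts(el.left)
        rp, rj = _walk_parts(el.right)
        return lp + rp, lj + rj + 1
    raise TypeError(f"cannot walk {el!r}")


def tree_census(tree: SemanticTree) -> tuple[int, int]:
    """(node count, edge count) of the drawn representation.

    Nodes are the distinct subjects, objects and values plus the
    query-item placeholder; edges are the triple predicates (including
    the query edge) plus one edge per time join.
    """
    nodes: set[str] = set()
    n_edges = 0
    n_joins = 0
    for el in tree.conditions:
        parts, joins = _walk_parts(el)
        n_joins += joins
        for s, _, o in parts:
            nodes.add(s)
            nodes.add(o)
        n_edges += len(parts)
    s, _, o = tree.query.part(tree.subject_class)
    nodes.add(s)
    nodes.add(o)
    n_edges += 1
    return len(nodes), n_edges + n_joins


# ---------------------------------------------------------------------------
# schema validation / scoring
# ---------------------------------------------------------------------------

def _iter_triples(el) -> Iterable:
    if isinstance(el, (EventTriple, AttrTriple, GenericTriple)):
        yield el
    elif isinstance(el, Group):
        for c in el.children:
            yield from _iter_triples(c)
    elif isinstance(el, TimeJoin):
        yield from _iter_triples(el.left)
        yield from _iter_triples(el.right)


def iter_triples(tree: SemanticTree) -> Iterable:
    for el in tree.conditions:
        yield from _iter_triples(el)


def _valid_parts(triple, schema: SchemaGraph) -> int:
    n = 0
    if isinstance(triple, EventTriple):
        if any(r.range == triple.object_cls for r in schema.lookup(triple.predicate)
               if r.domain == triple.subject):
            n += 1
        if triple.constraint is not None:
            attr = schema.attribute(triple.constraint.attribute)
            if attr is not None and attr.owner == triple.object_cls:
                n += 1
    elif isinstance(triple, AttrTriple):
        attr = schema.attribute(triple.attribute)
        if attr is not None and attr.owner == triple.subject:
            n += 1
    return n


def schema_score(tree: SemanticTree, schema: SchemaGraph) -> tuple[int, float]:
    """(number of schema-realizable triple parts, summed linking sigma)."""
    n = sum(_valid_parts(t, schema) for t in iter_triples(tree))
    return n, tree.sigma


def disambiguate(candidates: list[SemanticTree], schema: SchemaGraph) -> SemanticTree:
    """Pick the candidate with the best schema support.

    Score = (schema-realizable triple count, summed linking similarity);
    remaining ties break on the lexicographically smallest canonical
    serialization, which prefers the left-associated logical structure.
    """
    if not candidates:
        raise UnanswerableError("no candidate interpretation")
    keyed = []
    for t in candidates:
        n, sig = schema_score(t, schema)
        keyed.append(((-n, -sig, serialize(t)), t))
    keyed.sort(key=lambda kv: kv[0])
    return keyed[0][1]


# ---------------------------------------------------------------------------
# building candidate trees from parse forests
# ---------------------------------------------------------------------------

def _leaf_annotation(node: ParseTree, seq: TypedSequence):
    return seq.tokens[node.leaf_index].annotation


def _children_by_symbol(node: ParseTree) -> list[tuple[str, ParseTree]]:
    return [(c.symbol, c) for c in node.children]


class _Builder:
    def __init__(self, seq: TypedSequence, schema: SchemaGraph, cfg: PipelineConfig):
        self.seq = seq
        self.schema = schema
        self.cfg = cfg

    def _cands(self, node: ParseTree):
        return _leaf_annotation(node, self.seq).candidates

    # -- chunk conversions, each returning a list of alternatives ----------

    def timeblock(self, node: ParseTree) -> TimeFilter:
        leaves = [c for c in node.children]
        values = [int(self.seq.tokens[c.leaf_index].annotation.token)
                  for c in leaves if c.symbol == "TimeValue"]
        if len(values) == 2:
            lo, hi = min(values), max(values)
            return TimeFilter(lo, hi)
        if any(c.symbol == "LogicalOperator" for c in leaves):
            return TimeFilter(lo=values[0])  # open-ended ("since ...")
        return TimeFilter(values[0], values[0])

    def relation_condition(self, node: ParseTree) -> list[EventTriple]:
        tf: Optional[TimeFilter] = None
        negated = False
        rel_node = inst_node = None
        for sym, c in _children_by_symbol(node):
            if sym == "TimeBlock":
                tf = self.timeblock(c)
            elif sym == "Not":
                negated = True
            elif sym == "Relation":
                rel_node = c
            elif sym == "Instance":
                inst_node = c
        out: list[EventTriple] = []
        for rel in self._cands(rel_node):
            for inst in self._cands(inst_node):
                recs = [r for r in self.schema.lookup(rel.entity_id)
                        if r.range == inst.cls]
                for rec in recs:
                    out.append(EventTriple(
                        subject=rec.domain, predicate=rec.name,
                        object_label=inst.label, object_cls=inst.cls,
                        object_id=inst.entity_id, negated=negated,
                        time_filter=tf, sigma=rel.score + inst.score))
        return out

    def numeric_value(self, node: ParseTree) -> list[tuple[float, Optional[str]]]:
        num = unit = None
        for sym, c in _children_by_symbol(node):
            if sym == "Number":
                num = float(self.seq.tokens[c.leaf_index].annotation.token)
            elif sym == "Unit":
                unit = self._cands(c)[0].entity_id  # owner attribute of the unit
        return [(num, unit)]

    def property_value(self, node: ParseTree) -> list[tuple[Value, Optional[str], float]]:
        """Alternatives of (value, implied-attribute-or-None, sigma)."""
        child = node.children[0]
        if child.symbol == "EnumValue":
            return [(EnumV(c.entity_id), c.cls, c.score) for c in self._cands(child)]
        if child.symbol == "NumericValue":
            return [(NumV(v), u, 1.0) for v, u in self.numeric_value(child)]
        if child.symbol == "NumericRange":
            sub = child.children
            if sub[0].symbol == "ArithmeticOperator":
                op = self._cands(sub[0])[0].entity_id
                return [(Cmp(op, v), u, 1.0) for v, u in self.numeric_value(sub[1])]
            lo = self.numeric_value(sub[0])[0]
            hi = self.numeric_value(sub[2])[0]
            a, b = sorted((lo[0], hi[0]))
            return [(NumRange(a, b), lo[1] or hi[1], 1.0)]
        if child.symbol == "TimeBlock":
            return [(self.timeblock(child), None, 1.0)]
        raise ValueError(f"bad PropertyValue child {child.symbol}")

    def _anchor(self, cls: str) -> Optional[tuple[str, str]]:
        recs = sorted((r for r in self.schema.predicates if r.range == cls),
                      key=lambda r: r.name)
        return (recs[0].domain, recs[0].name) if recs else None

    def _value_ok(self, attr, value: Value) -> bool:
        if isinstance(value, EnumV):
            return attr.kind == "enum" and value.value in attr.enum_values
        if isinstance(value, TimeFilter):
            return attr.kind == "date"
        return attr.kind == "numeric"

    def property_condition(self, node: ParseTree) -> list:
        inst_node = prop_node = pv_node = None
        for sym, c in _children_by_symbol(node):
            if sym == "Instance":
                inst_node = c
            elif sym == "Property":
                prop_node = c
            elif sym == "PropertyValue":
                pv_node = c
        out: list = []
        for prop in self._cands(prop_node):
            attr = self.schema.attribute(prop.entity_id)
            if attr is None:
                continue
            for value, implied_attr, vsig in self.property_value(pv_node):
                if implied_attr is not None and implied_attr not in (attr.name, attr.owner):
                    continue
                if not self._value_ok(attr, value):
                    continue
                sigma = prop.score + vsig
                if inst_node is None:
                    if attr.owner == "patient":
                        out.append(AttrTriple("patient", attr.name, value, sigma=sigma))
                    elif attr.edge_field:
                        anchor = self._anchor(attr.owner)
                        if anchor:
                            out.append(EventTriple(
                                subject=anchor[0], predicate=anchor[1],
                                object_label=attr.owner, object_cls=attr.owner,
                                constraint=AttrConstraint(attr.name, value), sigma=sigma))
                else:
                    for inst in self._cands(inst_node):
                        if attr.owner != inst.cls or not attr.edge_field:
                            continue
                        anchor = self._anchor(inst.cls)
                        if anchor:
                            out.append(EventTriple(
                                subject=anchor[0], predicate=anchor[1],
                                object_label=inst.label, object_cls=inst.cls,
                                object_id=inst.entity_id,
                                constraint=AttrConstraint(attr.name, value),
                                sigma=sigma + inst.score))
        return out

    def condition(self, node: ParseTree) -> list:
        rhs = [c.symbol for c in node.children]
        if rhs == ["RelationCondition"]:
            return self.relation_condition(node.children[0])
        if rhs == ["PropertyCondition"]:
            return self.property_condition(node.children[0])
        if rhs == ["Condition", "LogicalOperator", "Condition"]:
            word = self._cands(node.children[1])[0].entity_id  # 'and' | 'or'
            out = []
            for l in self.condition(node.children[0]):
                for r in self.condition(node.children[2]):
                    out.append(_make_group(word, l, r))
                    if len(out) >= self.cfg.candidate_cap:
                        return out
            return out
        if rhs == ["RelationCondition", "TimeOperator", "Condition"]:
            cand = self._cands(node.children[1])[0]
            word = cand.entity_id  # canonical operator word ('after' / 'before')
            left_earlier = cand.entity_id != "before"
            out = []
            for l in self.relation_condition(node.children[0]):
                for r in self.condition(node.children[2]):
                    out.append(TimeJoin(word, l, r, left_earlier))
                    if len(out) >= self.cfg.candidate_cap:
                        return out
            return out
        raise ValueError(f"bad Condition expansion {rhs}")

    def query_item(self, node: ParseTree) -> list[QuerySpec]:
        rhs = [c.symbol for c in node.children]
        if rhs == ["StatisticOperator"]:
            stat = self._cands(node.children[0])[0].entity_id
            return [QuerySpec(stat, "cohort")]
        if rhs in (["Property", "StatisticOperator"], ["StatisticOperator", "Property"]):
            p = node.children[rhs.index("Property")]
            s = node.children[rhs.index("StatisticOperator")]
            stat = self._cands(s)[0].entity_id
            return [QuerySpec(stat, "property", c.entity_id) for c in self._cands(p)
                    if self.schema.attribute(c.entity_id) is not None]
        if rhs == ["Relation", "StatisticOperator", "Class"]:
            stat = self._cands(node.children[1])[0].entity_id
            cls = self._cands(node.children[2])[0].entity_id
            out = []
            for rel in self._cands(node.children[0]):
                for rec in self.schema.lookup(rel.entity_id):
                    if rec.range == cls or cls == "patient":
                        out.append(QuerySpec(stat, "related", rec.range, relation=rec.name))
            return out
        if rhs == ["Instance", "Property", "StatisticOperator"]:
            stat = self._cands(node.children[2])[0].entity_id
            out = []
            for inst in self._cands(node.children[0]):
                for prop in self._cands(node.children[1]):
                    attr = self.schema.attribute(prop.entity_id)
                    if attr is None or attr.owner != inst.cls or not attr.edge_field:
                        continue
                    out.append(QuerySpec(stat, "instance_property", attr.name,
                                         instance_label=inst.label,
                                         instance_id=inst.entity_id,
                                         instance_cls=inst.cls))
            return out
        raise ValueError(f"bad QueryItem expansion {rhs}")


def _make_group(op: str, left, right) -> Group:
    children: list = []
    for part in (left, right):
        if isinstance(part, Group) and part.op == op:
            children.extend(part.children)
        else:
            children.append(part)
    return Group(op, children)


def _element_sigma(el) -> float:
    return sum(t.sigma for t in _iter_triples(el))


def build(forest: ParseForest, schema: SchemaGraph, seq: TypedSequence,
          cfg: PipelineConfig = DEFAULT_CONFIG) -> list[SemanticTree]:
    """Candidate semantic trees for every (parse tree, entity assignment)."""
    if not forest:
        raise UnanswerableError("empty parse forest")
    out: list[SemanticTree] = []
    for ptree in forest.trees:
        builder = _Builder(seq, schema, cfg)
        # walk the S spine
        spine: list[tuple[str, ParseTree, Optional[ParseTree]]] = []
        node = ptree
        ok = True
        while True:
            rhs = [c.symbol for c in node.children]
            if rhs == ["QueryItem"]:
                spine.append(("query", node.children[0], None))
                break
            if rhs == ["QueryItem", "S"]:
                spine.append(("query", node.children[0], None))
            elif rhs == ["Condition", "S"]:
                spine.append(("cond", node.children[0], None))
            elif rhs == ["Condition", "Class", "S"]:
                spine.append(("cond", node.children[0], node.children[1]))
            else:
                ok = False
                break
            node = node.children[-1]
        if not ok or sum(1 for kind, *_ in spine if kind == "query") != 1:
            continue
        # subject class from the last trailing Class token, default patient
        subject = "patient"
        subject_sigma = 0.0
        for kind, _, cls_node in spine:
            if cls_node is not None:
                cands = builder._cands(cls_node)
                if cands:
                    subject = cands[0].entity_id
                    subject_sigma = cands[0].score
        # enumerate alternatives per chunk, capped cartesian product
        alt_lists: list[list] = []
        kinds: list[str] = []
        for kind, n, _ in spine:
            kinds.append(kind)
            alts = builder.query_item(n) if kind == "query" else builder.condition(n)
            if not alts:
                ok = False
                break
            alt_lists.append(alts[:cfg.candidate_cap])
        if not ok:
            continue
        for combo in itertools.islice(itertools.product(*alt_lists), cfg.candidate_cap):
            # alternatives are shared across combinations; copy so later
            # mutation (time attachment) cannot leak between candidates
            combo = copy.deepcopy(combo)
            conditions = [c for kind, c in zip(kinds, combo) if kind == "cond"]
            query = next(c for kind, c in zip(kinds, combo) if kind == "query")
            tree = SemanticTree(conditions=list(conditions), query=query,
                                subject_class=subject)
            tree.sigma = sum(_element_sigma(c) for c in conditions) + subject_sigma
            if query.statistic == "ratio":
                idx = _last_event_condition(tree.conditions)
                if idx is None:
                    continue
                tree.numerator_index = idx
            out.append(tree)
    return out


def _last_event_condition(conditions: list) -> Optional[int]:
    for i in range(len(conditions) - 1, -1, -1):
        if any(isinstance(t, EventTriple) and not t.negated
               for t in _iter_triples(conditions[i])):
            return i
    return None


# ---------------------------------------------------------------------------
# time attachment (implicit chronology)
# ---------------------------------------------------------------------------

def _positive_predicates(el) -> list[str]:
    return [t.predicate for t in _iter_triples(el) if isinstance(t, EventTriple)]


def _chain_head_predicate(join: TimeJoin) -> Optional[str]:
    node = join
    while isinstance(node, TimeJoin):
        node = node.left
    preds = _positive_predicates(node)
    return preds[0] if preds else None


def attach_time(tree: SemanticTree, schema: SchemaGraph) -> SemanticTree:
    """Extend explicit time chains with schema-implied chronology.

    Event predicates carry a relative chronology rank in the schema
    (diagnoses typically precede treatments, which precede follow-up
    tests).  When an explicit time chain is preceded by sibling relation
    conditions whose predicates all rank strictly below the chain head's,
    those conditions are absorbed as the earliest link of the chain.  No
    time join is ever created without an explicit time operator.
    """
    conds = list(tree.conditions)
    j = next((i for i, el in enumerate(conds) if isinstance(el, TimeJoin)), None)
    if j is None or j == 0:
        return tree
    join = conds[j]
    head = _chain_head_predicate(join)
    head_rank = schema.chronology_rank.get(head)
    if head_rank is None:
        return tree
    run_start = j
    for i in range(j - 1, -1, -1):
        preds = _positive_predicates(conds[i])
        triples = list(_iter_triples(conds[i]))
        if not preds or len(preds) != len(triples):
            break  # attribute conditions carry no chronology
        ranks = [schema.chronology_rank.get(p) for p in preds]
        if any(r is None or r >= head_rank for r in ranks):
            break
        run_start = i
    if run_start == j:
        return tree
    run = conds[run_start:j]
    group = run[0] if len(run) == 1 else Group("and", run)
    node = join
    while isinstance(node.left, TimeJoin):
        node = node.left
    node.left = TimeJoin(join.word, group, node.left, join.left_earlier)
    new_conds = conds[:run_start] + [join] + conds[j + 1:]
    if tree.numerator_index is not None and tree.numerator_index > j:
        tree.numerator_index -= j - run_start
    tree.conditions = new_conds
    return tree
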