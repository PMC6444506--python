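"""Translation of semantic trees into Cypher text (Neo4j 3.x dialect).

The translation decomposes into the three clauses: positive event
triples in conjunctive position become MATCH patterns radiating from the
patient node; attribute comparisons, NOT-pattern tests for negated
triples and timestamp inequalities for time joins go to WHERE; the
statistic determines RETURN.  Output is deterministic text with one
canonical whitespace; it is never executed by this package (the native
engine answers queries) but can be replayed against a live server.
"""

from __future__ import annotations

from .engine import UnsupportedOperationError
from .semantics import (AttrTriple, Cmp, EnumV, EventTriple, Group, NumRange, NumV,
                        SemanticTree, TimeFilter, TimeJoin)

_CMP = {"gt": ">", "lt": "<", "ge": ">=", "le": "<=", "eq": "="}


def _lit(v) -> str:
    if isinstance(v, str):
        return "'" + v.replace("'", "\\'") + "'"
    return f"{v:g}" if isinstance(v, float) else str(v)


def _value_clause(expr: str, value) -> str:
    if isinstance(value, EnumV):
        return f"{expr} = {_lit(value.value)}"
    if isinstance(value, NumV):
        return f"{expr} = {_lit(value.value)}"
    if isinstance(value, Cmp):
        return f"{expr} {_CMP[value.op]} {_lit(value.value)}"
    if isinstance(value, NumRange):
        return f"{expr} >= {_lit(value.lo)} AND {expr} <= {_lit(value.hi)}"
    if isinstance(value, TimeFilter):
        if value.lo is not None and value.lo == value.hi:
            return f"{expr} = {value.lo}"
        clauses = []
        if value.lo is not None:
            clauses.append(f"{expr} >= {value.lo}")
        if value.hi is not None:
            clauses.append(f"{expr} <= {value.hi}")
        return " AND ".join(clauses)
    raise TypeError(f"cannot render value {value!r}")


class _Translator:
    def __init__(self, tree: SemanticTree, schema):
        self.tree = tree
        self.schema = schema
        self.matches: list[str] = [f"(p:`{tree.subject_class}`)"]
        self.where: list[str] = []
        self.edge_vars: dict[int, str] = {}  # id(triple) -> variable
        self.counter = 0

    def _node_pattern(self, t: EventTriple, var: str = "") -> str:
        name = f" {{name: {_lit(t.object_label)}}}" if t.object_id is not None else ""
        return f"({var}:`{t.object_cls}`{name})"

    def _edge_field(self, t: EventTriple) -> str:
        attr = self.schema.attribute(t.constraint.attribute)
        return attr.edge_field if attr and attr.edge_field else t.constraint.attribute

    def _pattern_text(self, t: EventTriple) -> str:
        return f"(p)-[:`{t.predicate}`]->{self._node_pattern(t)}"

    def add_positive(self, t: EventTriple) -> None:
        self.counter += 1
        rv, nv = f"r{self.counter}", f"n{self.counter}"
        self.edge_vars[id(t)] = rv
        self.matches.append(f"(p)-[{rv}:`{t.predicate}`]->{self._node_pattern(t, nv)}")
        if t.constraint is not None:
            self.where.append(_value_clause(f"{rv}.`{self._edge_field(t)}`",
                                            t.constraint.value))
        if t.time_filter is not None:
            self.where.append(_value_clause(f"{rv}.timestamp", t.time_filter))

    def boolean_text(self, el) -> str:
        """Render an element as a boolean WHERE expression (no edge vars)."""
        if isinstance(el, EventTriple):
            text = self._pattern_text(el)
            if el.constraint is not None or el.time_filter is not None:
                raise UnsupportedOperationError(
                    "filtered event pattern in boolean position")
            return f"NOT {text}" if el.negated else text
        if isinstance(el, AttrTriple):
            text = _value_clause(f"p.`{el.attribute}`", el.value)
            return f"NOT ({text})" if el.negated else f"({text})"
        if isinstance(el, Group):
            sep = " AND " if el.op == "and" else " OR "
            return "(" + sep.join(self.boolean_text(c) for c in el.children) + ")"
        raise UnsupportedOperationError(
            f"{type(el).__name__} cannot be rendered as a boolean predicate")

    def add_element(self, el) -> None:
        if isinstance(el, EventTriple):
            if el.negated:
                self.where.append(self.boolean_text(el))
            else:
                self.add_positive(el)
        elif isinstance(el, AttrTriple):
            self.where.append(self.boolean_text(el))
        elif isinstance(el, Group):
            if el.op == "and":
                for c in el.children:
                    self.add_element(c)
            else:
                self.where.append(self.boolean_text(el))
        elif isinstance(el, TimeJoin):
            self.add_element(el.left)
            self.add_element(el.right)
            lvars = self._join_vars(el.left)
            rvars = self._join_vars(el.right)
            if not lvars or not rvars:
                raise UnsupportedOperationError(
                    "time join over a disjunctive operand")
            op = "<" if el.left_earlier else ">"
            for lv in lvars:
                for rv in rvars:
                    self.where.append(f"{lv}.timestamp {op} {rv}.timestamp")
        else:
            raise UnsupportedOperationError(f"cannot translate {type(el).__name__}")

    def _join_vars(self, el) -> list[str]:
        if isinstance(el, EventTriple):
            return [self.edge_vars[id(el)]] if id(el) in self.edge_vars else []
        if isinstance(el, Group) and el.op == "and":
            return [v for c in el.children for v in self._join_vars(c)]
        if isinstance(el, TimeJoin):
            return self._join_vars(el.left) + self._join_vars(el.right)
        return []

    def return_clause(self) -> str:
        q = self.tree.query
        stat = q.statistic
        if stat == "count":
            return "RETURN count(DISTINCT p) AS value"
        if stat == "list":
            if q.target_kind == "related":
                self.counter += 1
                self.matches.append(f"(p)-[:`{q.relation}`]->(t:`{q.target}`)")
                return "RETURN DISTINCT t.label AS value ORDER BY value"
            if q.target_kind == "property":
                return f"RETURN DISTINCT p.id AS id, p.`{q.target}` AS value ORDER BY id"
            return "RETURN DISTINCT p.id AS id, p.label AS label ORDER BY id"
        if stat in ("sum", "avg"):
            if q.target_kind == "instance_property":
                attr = self.schema.attribute(q.target)
                self.matches.append(
                    f"(p)-[rq:`{self._anchor_pred(q.instance_cls)}`]->"
                    f"(:`{q.instance_cls}` {{name: {_lit(q.instance_label)}}})")
                return f"RETURN {stat}(rq.`{attr.edge_field}`) AS value"
            return f"RETURN {stat}(p.`{q.target}`) AS value"
        if stat == "distribution":
            if q.target_kind == "related":
                self.matches.append(f"(p)-[:`{q.relation}`]->(t:`{q.target}`)")
                return ("RETURN t.label AS bucket, count(DISTINCT p) AS n "
                        "ORDER BY bucket")
            return (f"RETURN p.`{q.target}` AS bucket, count(DISTINCT p) AS n "
                    "ORDER BY bucket")
        if stat == "ratio":
            num = self.tree.conditions[self.tree.numerator_index]
            text = self.boolean_text(num)
            return ("RETURN toFloat(count(DISTINCT CASE WHEN "
                    f"{text} THEN p END)) / count(DISTINCT p) AS value")
        raise UnsupportedOperationError(f"statistic {stat!r} is not supported")

    def _anchor_pred(self, cls: str) -> str:
        recs = sorted((r for r in self.schema.predicates if r.range == cls),
                      key=lambda r: r.name)
        if not recs:
            raise UnsupportedOperationError(f"no predicate reaches class {cls!r}")
        return recs[0].name


def to_cypher(tree: SemanticTree, schema) -> str:
    """Deterministic Cypher text for a schema-valid semantic tree."""
    tr = _Translator(tree, schema)
    for i, el in enumerate(tree.conditions):
        if i == tree.numerator_index:
            continue  # the ratio numerator is realized inside RETURN
        tr.add_element(el)
    ret = tr.return_clause()
    lines = ["MATCH " + ", ".join(tr.matches)]
    if tr.where:
        lines.append("WHERE " + " AND ".join(tr.where))
    lines.append(ret)
    return "\n".join(lines)
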