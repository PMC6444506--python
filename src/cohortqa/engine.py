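"""Native execution of semantic trees over the in-memory patient graph.

Semantics: a patient satisfies a positive event triple iff a matching
edge (object, edge-attribute and timestamp filters included) exists, and
a negated triple iff no matching edge exists.  And/Or combine satisfying
patient sets by intersection/union.  A time join requires *witness*
edges: one timestamped edge per positive event triple in the join such
that every (left, right) pair respects the join's direction (strict
inequality; same-day events satisfy neither "after" nor "before").
Or-branches inside a join are expanded into alternative conjunctive
scenarios, and any scenario with a feasible witness assignment passes.

:func:`oracle_execute` re-implements the same contract as a naive
per-patient exhaustive scan with no indexing; it exists for testing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

from .config import DEFAULT_CONFIG, PipelineConfig
from .kg_store import Edge, PatientGraph
from .semantics import (AttrTriple, Cmp, EnumV, EventTriple, GenericTriple, Group,
                        NumRange, NumV, SemanticTree, TimeFilter, TimeJoin,
                        _iter_triples)


class StatisticTypeError(TypeError):
    """The requested aggregate is not defined for the target's value kind."""


class UnsupportedOperationError(ValueError):
    """The construct cannot be realized (e.g. grouped sort / top-N)."""


@dataclass
class ResultSet:
    """Statistic output with its statistics-type tag.

    ``payload``: rows (list), scalar (count/sum/avg/ratio), or an ordered
    {group: count} mapping for distributions.  ``excluded`` counts cohort
    members skipped because the target attribute was missing;
    ``undefined`` marks a ratio over an empty cohort.
    """

    type: str
    payload: object = None
    excluded: int = 0
    undefined: bool = False

    def to_json(self) -> str:
        return json.dumps({"type": self.type, "payload": self.payload,
                           "excluded": self.excluded, "undefined": self.undefined},
                          ensure_ascii=False, sort_keys=True)


def results_equal(a: ResultSet, b: ResultSet, rtol: float = 1e-9) -> bool:
    if a.type != b.type or a.undefined != b.undefined:
        return False
    if a.undefined:
        return True
    if isinstance(a.payload, float) or isinstance(b.payload, float):
        if a.payload is None or b.payload is None:
            return a.payload == b.payload
        scale = max(abs(a.payload), abs(b.payload), 1e-300)
        return abs(a.payload - b.payload) <= rtol * scale
    return a.payload == b.payload


# ---------------------------------------------------------------------------
# value matching
# ---------------------------------------------------------------------------

def _value_matches(raw, value) -> bool:
    if raw is None:
        return False
    if isinstance(value, EnumV):
        return str(raw) == value.value
    try:
        x = float(raw)
    except (TypeError, ValueError):
        return False
    if isinstance(value, NumV):
        return x == value.value
    if isinstance(value, Cmp):
        return {"gt": x > value.value, "lt": x < value.value,
                "ge": x >= value.value, "le": x <= value.value,
                "eq": x == value.value}[value.op]
    if isinstance(value, NumRange):
        return value.lo <= x <= value.hi
    if isinstance(value, TimeFilter):
        return value.contains(int(x))
    return False


def _edge_matches(e: Edge, t: EventTriple, g: PatientGraph) -> bool:
    if e.predicate != t.predicate:
        return False
    if t.object_id is not None:
        if e.target != t.object_id:
            return False
    else:
        node = g.data.nodes.get(e.target)
        if node is None or node.cls != t.object_cls:
            return False
    if t.constraint is not None:
        attr = g.schema.attribute(t.constraint.attribute)
        raw = getattr(e, attr.edge_field) if attr and attr.edge_field else None
        if not _value_matches(raw, t.constraint.value):
            return False
    if t.time_filter is not None:
        if e.timestamp is None or not t.time_filter.contains(e.timestamp):
            return False
    return True


# ---------------------------------------------------------------------------
# scenario expansion for time joins
# ---------------------------------------------------------------------------

def _scenarios(el) -> list[tuple[list[EventTriple], list[tuple]]]:
    """Conjunctive readings: (positive event triples, ordering pairs)."""
    if isinstance(el, EventTriple):
        return [([el] if not el.negated else [], [])]
    if isinstance(el, (AttrTriple, GenericTriple)):
        return [([], [])]
    if isinstance(el, Group):
        if el.op == "or":
            out = []
            for c in el.children:
                out.extend(_scenarios(c))
            return out
        combos = [([], [])]
        for c in el.children:
            combos = [(ts + cts, ps + cps)
                      for ts, ps in combos for cts, cps in _scenarios(c)]
        return combos
    if isinstance(el, TimeJoin):
        out = []
        for lts, lps in _scenarios(el.left):
            for rts, rps in _scenarios(el.right):
                pairs = lps + rps + [(l, r, el.left_earlier) for l in lts for r in rts]
                out.append((lts + rts, pairs))
        return out
    raise TypeError(f"cannot expand {el!r}")


def _witness_assignment(domains: dict[int, list[int]],
                        pairs: list[tuple], triples: list[EventTriple],
                        cap: int) -> bool:
    """Backtracking search for timestamps satisfying all ordering pairs."""
    ids = [id(t) for t in triples]
    order = sorted(range(len(triples)), key=lambda i: len(domains[ids[i]]))
    chosen: dict[int, int] = {}
    budget = [cap]

    def consistent(tid: int, ts: int) -> bool:
        for l, r, left_earlier in pairs:
            lt = ts if id(l) == tid else chosen.get(id(l))
            rt = ts if id(r) == tid else chosen.get(id(r))
            if lt is None or rt is None:
                continue
            if left_earlier and not lt < rt:
                return False
            if not left_earlier and not lt > rt:
                return False
        return True

    def rec(k: int) -> bool:
        if budget[0] <= 0:
            return False
        if k == len(order):
            return True
        tid = ids[order[k]]
        for ts in domains[tid]:
            budget[0] -= 1
            if consistent(tid, ts):
                chosen[tid] = ts
                if rec(k + 1):
                    return True
                del chosen[tid]
        return False

    return rec(0)


# ---------------------------------------------------------------------------
# indexed executor
# ---------------------------------------------------------------------------

class _Executor:
    def __init__(self, g: PatientGraph, subject_class: str, cfg: PipelineConfig):
        self.g = g
        self.cfg = cfg
        self.subjects = {n.id for n in g.data.nodes.values() if n.cls == subject_class}
        self.by_source: dict[str, list[Edge]] = {}
        for e in g.data.edges:
            self.by_source.setdefault(e.source, []).append(e)

    def matching_edges(self, pid: str, t: EventTriple) -> list[Edge]:
        return [e for e in self.by_source.get(pid, []) if _edge_matches(e, t, self.g)]

    def sat(self, el) -> set[str]:
        if isinstance(el, EventTriple):
            matched = {pid for pid in self.subjects if self.matching_edges(pid, el)}
            return self.subjects - matched if el.negated else matched
        if isinstance(el, AttrTriple):
            matched = set()
            for pid in self.subjects:
                raw = self.g.data.nodes[pid].attrs.get(el.attribute)
                if _value_matches(raw, el.value):
                    matched.add(pid)
            return self.subjects - matched if el.negated else matched
        if isinstance(el, Group):
            sets = [self.sat(c) for c in el.children]
            if el.op == "or":
                out: set[str] = set()
                for s in sets:
                    out |= s
                return out
            out = set(self.subjects)
            for s in sets:
                out &= s
            return out
        if isinstance(el, TimeJoin):
            base = self.sat(el.left) & self.sat(el.right)
            scenarios = _scenarios(el)
            ok = set()
            for pid in base:
                for triples, pairs in scenarios:
                    domains = {}
                    feasible = True
                    for t in triples:
                        ts_list = sorted({e.timestamp for e in self.matching_edges(pid, t)
                                          if e.timestamp is not None})
                        if not ts_list:
                            feasible = False
                            break
                        domains[id(t)] = ts_list
                    if feasible and _witness_assignment(domains, pairs, triples,
                                                        self.cfg.witness_cap):
                        ok.add(pid)
                        break
            return ok
        raise TypeError(f"cannot evaluate {el!r}")


def cohort_of(tree: SemanticTree, g: PatientGraph,
              cfg: PipelineConfig = DEFAULT_CONFIG) -> tuple[set[str], Optional[set[str]]]:
    """(cohort ids, ratio-numerator ids or None)."""
    ex = _Executor(g, tree.subject_class, cfg)
    cohort = set(ex.subjects)
    for i, el in enumerate(tree.conditions):
        if i == tree.numerator_index:
            continue
        cohort &= ex.sat(el)
    numerator = None
    if tree.numerator_index is not None:
        numerator = ex.sat(tree.conditions[tree.numerator_index]) & cohort
    return cohort, numerator


def execute(tree: SemanticTree, g: PatientGraph,
            cfg: PipelineConfig = DEFAULT_CONFIG) -> ResultSet:
    cohort, numerator = cohort_of(tree, g, cfg)
    if tree.query.statistic == "ratio":
        if numerator is None:
            raise UnsupportedOperationError("ratio requires a relation condition")
        if not cohort:
            return ResultSet("ratio", None, undefined=True)
        return ResultSet("ratio", len(numerator) / len(cohort))
    return compute_statistic(cohort, tree.query, g, cfg)


# ---------------------------------------------------------------------------
# statistics over a computed cohort
# ---------------------------------------------------------------------------

def _bin_label(lo: float, width: float) -> str:
    return f"[{lo:g}, {lo + width:g})"


def _bin_numeric(values: list[float], name: str, cfg: PipelineConfig) -> dict[str, int]:
    if not values:
        return {}
    if name == "age":
        width = float(cfg.age_bin_width)
        anchored = 0.0
    else:
        lo, hi = min(values), max(values)
        width = (hi - lo) / cfg.n_bins or 1.0
        anchored = lo
    out: dict[str, int] = {}
    for v in values:
        k = int((v - anchored) // width)
        if name != "age":
            k = min(k, cfg.n_bins - 1)
        out[_bin_label(anchored + k * width, width)] = \
            out.get(_bin_label(anchored + k * width, width), 0) + 1
    return dict(sorted(out.items(), key=lambda kv: float(kv[0].split(",")[0][1:])))


def _target_values(cohort: set[str], query, g: PatientGraph) -> tuple[list, int]:
    """Raw values of the query target over the cohort + excluded count."""
    values: list = []
    excluded = 0
    if query.target_kind == "property":
        for pid in sorted(cohort):
            raw = g.data.nodes[pid].attrs.get(query.target)
            if raw is None:
                excluded += 1
            else:
                values.append(raw)
    elif query.target_kind == "instance_property":
        attr = g.schema.attribute(query.target)
        for pid in sorted(cohort):
            got = False
            for e in g.data.edges:
                if e.source != pid or e.target != query.instance_id:
                    continue
                raw = getattr(e, attr.edge_field) if attr.edge_field else None
                if raw is not None:
                    values.append(raw)
                    got = True
            if not got:
                excluded += 1
    return values, excluded


def compute_statistic(cohort: set[str], query, g: PatientGraph,
                      cfg: PipelineConfig = DEFAULT_CONFIG) -> ResultSet:
    stat = query.statistic
    if stat == "count":
        return ResultSet("count", len(cohort))

    if stat == "list":
        if query.target_kind == "related":
            labels = sorted({g.data.nodes[e.target].label for e in g.data.edges
                             if e.source in cohort and e.predicate == query.relation
                             and g.data.nodes.get(e.target)})
            return ResultSet("list", labels)
        rows = []
        for pid in sorted(cohort):
            n = g.data.nodes[pid]
            row = {"id": n.id, "label": n.label}
            if query.target_kind == "property":
                row[query.target] = n.attrs.get(query.target)
            rows.append(row)
        return ResultSet("list", rows)

    if stat in ("sum", "avg"):
        if query.target_kind == "property":
            attr = g.schema.attribute(query.target)
            if attr is None or attr.kind != "numeric":
                raise StatisticTypeError(f"{stat} over non-numeric property {query.target!r}")
        values, excluded = _target_values(cohort, query, g)
        nums = [float(v) for v in values]
        if not nums:
            return ResultSet(stat, None, excluded=excluded, undefined=True)
        total = sum(nums)
        return ResultSet(stat, total if stat == "sum" else total / len(nums),
                         excluded=excluded)

    if stat == "distribution":
        if query.target_kind == "related":
            counts: dict[str, int] = {}
            for pid in sorted(cohort):
                labels = {g.data.nodes[e.target].label for e in g.data.edges
                          if e.source == pid and e.predicate == query.relation
                          and g.data.nodes.get(e.target)}
                for lab in labels:
                    counts[lab] = counts.get(lab, 0) + 1
            return ResultSet("distribution", dict(sorted(counts.items())))
        values, excluded = _target_values(cohort, query, g)
        attr = g.schema.attribute(query.target) if query.target else None
        if attr is not None and attr.kind == "numeric":
            payload = _bin_numeric([float(v) for v in values], attr.name, cfg)
        else:
            payload = {}
            for v in values:
                payload[str(v)] = payload.get(str(v), 0) + 1
            payload = dict(sorted(payload.items()))
        return ResultSet("distribution", payload, excluded=excluded)

    raise UnsupportedOperationError(f"statistic {stat!r} is not supported")


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def _o_edge_ok(e: Edge, t: EventTriple, g: PatientGraph) -> bool:
    return _edge_matches(e, t, g)


def _o_scenarios(el):
    # independent re-derivation of the conjunctive readings
    if isinstance(el, EventTriple):
        return [([el], [])] if not el.negated else [([], [])]
    if isinstance(el, (AttrTriple, GenericTriple)):
        return [([], [])]
    if isinstance(el, Group) and el.op == "or":
        return [s for c in el.children for s in _o_scenarios(c)]
    if isinstance(el, Group):
        acc = [([], [])]
        for c in el.children:
            acc = [(a + b, pa + pb) for a, pa in acc for b, pb in _o_scenarios(c)]
        return acc
    if isinstance(el, TimeJoin):
        out = []
        for lt, lp in _o_scenarios(el.left):
            for rt, rp in _o_scenarios(el.right):
                out.append((lt + rt,
                            lp + rp + [(a, b, el.left_earlier) for a in lt for b in rt]))
        return out
    raise TypeError(el)


def _o_satisfies(pid: str, el, g: PatientGraph) -> bool:
    if isinstance(el, EventTriple):
        found = any(e.source == pid and _o_edge_ok(e, el, g) for e in g.data.edges)
        return not found if el.negated else found
    if isinstance(el, AttrTriple):
        ok = _value_matches(g.data.nodes[pid].attrs.get(el.attribute), el.value)
        return not ok if el.negated else ok
    if isinstance(el, Group):
        op = all if el.op == "and" else any
        return op(_o_satisfies(pid, c, g) for c in el.children)
    if isinstance(el, TimeJoin):
        if not (_o_satisfies(pid, el.left, g) and _o_satisfies(pid, el.right, g)):
            return False
        for triples, pairs in _o_scenarios(el):
            pools = []
            for t in triples:
                pool = [e.timestamp for e in g.data.edges
                        if e.source == pid and e.timestamp is not None
                        and _o_edge_ok(e, t, g)]
                pools.append(pool)
            if any(not pool for pool in pools):
                continue
            index = {id(t): k for k, t in enumerate(triples)}
            for combo in itertools.islice(itertools.product(*pools), 100000):
                good = True
                for l, r, left_earlier in pairs:
                    lt, rt = combo[index[id(l)]], combo[index[id(r)]]
                    if (left_earlier and not lt < rt) or \
                            (not left_earlier and not lt > rt):
                        good = False
                        break
                if good:
                    return True
        return False
    raise TypeError(el)


def oracle_execute(tree: SemanticTree, g: PatientGraph,
                   cfg: PipelineConfig = DEFAULT_CONFIG) -> ResultSet:
    """Same contract as :func:`execute`, via naive exhaustive evaluation."""
    subjects = sorted(n.id for n in g.data.nodes.values()
                      if n.cls == tree.subject_class)
    cohort = set()
    for pid in subjects:
        if all(_o_satisfies(pid, el, g)
               for i, el in enumerate(tree.conditions) if i != tree.numerator_index):
            cohort.add(pid)
    if tree.query.statistic == "ratio":
        if tree.numerator_index is None:
            raise UnsupportedOperationError("ratio requires a relation condition")
        if not cohort:
            return ResultSet("ratio", None, undefined=True)
        num = {pid for pid in cohort
               if _o_satisfies(pid, tree.conditions[tree.numerator_index], g)}
        return ResultSet("ratio", len(num) / len(cohort))
    return compute_statistic(cohort, tree.query, g, cfg)
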