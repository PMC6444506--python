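"""In-memory patient knowledge graph G = <Gs, Gd, R>.

The graph follows the six-class EMR shape used throughout the package:
a ``patient`` class connected to ``disease``, ``drug``, ``test``,
``procedure`` and ``hospitalization`` event classes by time-stamped
edges, mirroring the OHDSI-style tables (PERSON, CONDITION_OCCURRENCE,
DRUG_EXPOSURE, MEASUREMENT, PROCEDURE_OCCURRENCE, VISIT_OCCURRENCE)
after conversion to a property graph.

``Gs`` (:class:`SchemaGraph`) holds classes, predicate records with
domain/range, predicate synonyms and an attribute registry.  ``Gd``
(:class:`DataGraph`) holds instance nodes and edge triples; the typing
relation ``R`` is carried by each node's ``cls`` field.  Everything is
plain in-memory maps — Cypher is an *output dialect* of this package,
never a storage backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class GraphFormatError(ValueError):
    """A CSV file does not conform to the documented column layout."""


class GraphIntegrityError(ValueError):
    """Referential integrity of the loaded graph is violated."""


# ---------------------------------------------------------------------------
# schema graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredicateRecord:
    """One (name, domain, range) property edge of the schema graph."""

    name: str
    domain: str
    range: str


@dataclass(frozen=True)
class AttributeSpec:
    """A registered attribute: owner class, value kind, units, enum values.

    ``edge_field`` names the data-edge column that carries the value when
    the owner is an event class (test results live on DidTest edges, not
    on the shared test catalog node).
    """

    name: str
    owner: str
    kind: str  # 'numeric' | 'enum' | 'date' | 'text'
    units: tuple[str, ...] = ()
    enum_values: tuple[str, ...] = ()
    edge_field: str | None = None


@dataclass
class SchemaGraph:
    classes: set[str] = field(default_factory=set)
    predicates: list[PredicateRecord] = field(default_factory=list)
    predicate_synonyms: dict[str, str] = field(default_factory=dict)
    attributes: dict[str, AttributeSpec] = field(default_factory=dict)
    #: relative chronology of event predicates (smaller = typically earlier);
    #: used by the implicit-chronology heuristic of the semantic builder
    chronology_rank: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        datatypes = {"numeric", "enum", "date", "text"}
        seen: set[PredicateRecord] = set()
        for rec in self.predicates:
            if rec.domain not in self.classes:
                raise GraphIntegrityError(f"predicate {rec.name!r}: unknown domain {rec.domain!r}")
            if rec.range not in self.classes and rec.range not in datatypes:
                raise GraphIntegrityError(f"predicate {rec.name!r}: unknown range {rec.range!r}")
            if rec in seen:
                raise GraphIntegrityError(f"duplicate predicate record {rec}")
            seen.add(rec)
        units: dict[str, str] = {}
        enums: dict[str, str] = {}
        for attr in self.attributes.values():
            for u in attr.units:
                if u in units:
                    raise GraphIntegrityError(f"unit {u!r} owned by both {units[u]!r} and {attr.name!r}")
                units[u] = attr.name
            for v in attr.enum_values:
                if v in enums:
                    raise GraphIntegrityError(f"enum value {v!r} owned by both {enums[v]!r} and {attr.name!r}")
                enums[v] = attr.name

    # --- lookups -----------------------------------------------------------

    def lookup(self, name: str) -> list[PredicateRecord]:
        """All predicate records whose canonical name or synonym matches."""
        canonical = self.predicate_synonyms.get(name, name)
        return [rec for rec in self.predicates if rec.name == canonical]

    def attribute(self, name: str) -> AttributeSpec | None:
        return self.attributes.get(name)

    def attributes_by_unit(self, unit: str) -> list[AttributeSpec]:
        return [a for a in self.attributes.values() if unit in a.units]

    def attributes_by_enum(self, value: str) -> list[AttributeSpec]:
        return [a for a in self.attributes.values() if value in a.enum_values]

    def event_predicates(self) -> set[str]:
        return {rec.name for rec in self.predicates if rec.range in self.classes}


def schema_lookup(gs: SchemaGraph, predicate_or_synonym: str) -> list[PredicateRecord]:
    """Resolve a verb (canonical name or registered synonym) to its records."""
    return gs.lookup(predicate_or_synonym)


def default_schema() -> SchemaGraph:
    """The bundled six-class EMR schema."""
    classes = {"patient", "disease", "drug", "test", "procedure", "hospitalization"}
    predicates = [
        PredicateRecord("suffer", "patient", "disease"),
        PredicateRecord("take", "patient", "drug"),
        PredicateRecord("have test", "patient", "test"),
        PredicateRecord("operate", "patient", "procedure"),
        PredicateRecord("in hospital", "patient", "hospitalization"),
        PredicateRecord("sex", "patient", "enum"),
        PredicateRecord("age", "patient", "numeric"),
        PredicateRecord("birthday", "patient", "date"),
    ]
    synonyms = {
        "diagnose": "suffer", "suffer from": "suffer", "with": "suffer",
        "eat": "take", "took": "take", "use": "take",
        "did test": "have test", "tested": "have test",
        "did operate": "operate", "underwent": "operate",
        "admitted": "in hospital", "hospitalized": "in hospital",
    }
    attributes = {
        "sex": AttributeSpec("sex", "patient", "enum", enum_values=("female", "male")),
        "age": AttributeSpec("age", "patient", "numeric", units=("years old", "岁")),
        "birthday": AttributeSpec("birthday", "patient", "date"),
        "test result": AttributeSpec(
            "test result", "test", "enum",
            enum_values=("low", "normal", "high"), edge_field="result"),
        "result value": AttributeSpec(
            "result value", "test", "numeric", edge_field="value"),
        "stay days": AttributeSpec(
            "stay days", "hospitalization", "numeric", units=("day", "days", "天"),
            edge_field="value"),
    }
    ranks = {"suffer": 0, "in hospital": 1, "take": 2, "operate": 2, "have test": 3}
    gs = SchemaGraph(classes, predicates, synonyms, attributes, ranks)
    gs.validate()
    return gs


# ---------------------------------------------------------------------------
# data graph
# ---------------------------------------------------------------------------

@dataclass
class Node:
    id: str
    label: str
    cls: str
    attrs: dict[str, object] = field(default_factory=dict)


@dataclass
class Edge:
    source: str
    predicate: str
    target: str
    timestamp: int | None = None  # canonical yyyymmdd; None = missing marker
    value: float | None = None
    result: str | None = None


@dataclass
class DataGraph:
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)


@dataclass(frozen=True)
class TerminologyLink:
    entity_id: str
    term_id: str
    kind: str  # 'sameAs' | 'equivalentClass'
    score: float

    def __post_init__(self) -> None:
        if self.kind not in ("sameAs", "equivalentClass"):
            raise ValueError(f"bad link kind {self.kind!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"link score {self.score} outside [0, 1]")


@dataclass
class PatientGraph:
    """G = <Gs, Gd, R> plus terminology links."""

    schema: SchemaGraph
    data: DataGraph = field(default_factory=DataGraph)
    terminology_links: list[TerminologyLink] = field(default_factory=list)

    @property
    def typing(self) -> set[tuple[str, str]]:
        """The typing relation R as (instance id, class id) pairs."""
        return {(n.id, n.cls) for n in self.data.nodes.values()}

    def patients(self) -> list[Node]:
        return self.nodes_of_class("patient")

    def nodes_of_class(self, cls: str) -> list[Node]:
        return [n for n in self.data.nodes.values() if n.cls == cls]

    def validate(self) -> None:
        self.schema.validate()
        bad: list[str] = []
        for i, e in enumerate(self.data.edges):
            if e.source not in self.data.nodes:
                bad.append(f"row {i}: source {e.source!r}")
            if e.target not in self.data.nodes and e.predicate in self.schema.event_predicates():
                bad.append(f"row {i}: target {e.target!r}")
        if bad:
            raise GraphIntegrityError("dangling edge endpoints: " + "; ".join(bad))
        for n in self.data.nodes.values():
            if n.cls not in self.schema.classes:
                raise GraphIntegrityError(f"node {n.id!r} has unregistered class {n.cls!r}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_NODE_REQUIRED = ("id", "label", "class")
_EDGE_REQUIRED = ("source_id", "predicate", "target_id", "timestamp")
_EDGE_OPTIONAL = ("value", "result")


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    for col in required:
        if col not in df.columns:
            raise GraphFormatError(f"{path}: missing column {col!r}")


def load_graph(node_files: Iterable, edge_files: Iterable,
               schema: SchemaGraph | None = None) -> PatientGraph:
    """Load a patient graph from node/edge CSV files (UTF-8, header row)."""
    g = PatientGraph(schema or default_schema())
    for path in node_files:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_columns(df, _NODE_REQUIRED, path)
        attr_cols = [c for c in df.columns if c not in _NODE_REQUIRED]
        for rec in df.to_dict(orient="records"):
            attrs: dict[str, object] = {}
            for c in attr_cols:
                raw = rec[c]
                if raw == "":
                    continue
                try:
                    attrs[c] = float(raw) if "." in raw else int(raw)
                except ValueError:
                    attrs[c] = raw
            node = Node(rec["id"], rec["label"], rec["class"], attrs)
            if node.id in g.data.nodes:
                raise GraphIntegrityError(f"{path}: duplicate node id {node.id!r}")
            g.data.nodes[node.id] = node
    for path in edge_files:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_columns(df, _EDGE_REQUIRED, path)
        for rec in df.to_dict(orient="records"):
            ts = int(rec["timestamp"]) if rec["timestamp"] != "" else None
            value = None
            if rec.get("value", "") != "":
                value = float(rec["value"])
            result = rec.get("result") or None
            g.data.edges.append(Edge(rec["source_id"], rec["predicate"],
                                     rec["target_id"], ts, value, result))
    g.validate()
    return g


def save_graph(g: PatientGraph, out_dir) -> tuple[Path, Path]:
    """Write the data graph back out as nodes.csv / edges.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attr_cols = sorted({k for n in g.data.nodes.values() for k in n.attrs})
    node_rows = []
    for n in sorted(g.data.nodes.values(), key=lambda n: n.id):
        row = {"id": n.id, "label": n.label, "class": n.cls}
        for c in attr_cols:
            row[c] = n.attrs.get(c, "")
        node_rows.append(row)
    nodes_path = out / "nodes.csv"
    pd.DataFrame(node_rows, columns=list(_NODE_REQUIRED) + attr_cols).to_csv(
        nodes_path, index=False)
    edge_rows = [{
        "source_id": e.source, "predicate": e.predicate, "target_id": e.target,
        "timestamp": "" if e.timestamp is None else e.timestamp,
        "value": "" if e.value is None else e.value,
        "result": e.result or "",
    } for e in g.data.edges]
    edges_path = out / "edges.csv"
    pd.DataFrame(edge_rows, columns=list(_EDGE_REQUIRED) + list(_EDGE_OPTIONAL)).to_csv(
        edges_path, index=False)
    return nodes_path, edges_path


# ---------------------------------------------------------------------------
# statistics and terminology linking
# ---------------------------------------------------------------------------

def average_degree(n_vertices: int, n_edges: int) -> float:
    """Undirected average degree 2|E|/|V| rounded to 2 decimals."""
    if n_vertices == 0:
        return 0.0
    return round(2 * n_edges / n_vertices, 2)


def graph_stats(g: PatientGraph) -> dict[str, float]:
    n, m = len(g.data.nodes), len(g.data.edges)
    return {"vertices": n, "edges": m, "average_degree": average_degree(n, m)}


def link_terminology(g: PatientGraph, terminology_entries: Iterable[tuple],
                     threshold: float = 0.75) -> list[TerminologyLink]:
    """owl:sameAs links between data entities and terminology entries.

    ``terminology_entries`` are (term_id, surface, synonyms) tuples.  Each
    data entity links to at most its best-scoring entry with averaged
    string similarity >= ``threshold``.
    """
    from .linking import entity_score  # local import: avoids a module cycle

    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    entries = [(tid, surf, tuple(syns)) for tid, surf, syns in terminology_entries]
    links: list[TerminologyLink] = []
    for node in sorted(g.data.nodes.values(), key=lambda n: n.id):
        if node.cls == "patient":
            continue
        best: tuple[float, str] | None = None
        for tid, surf, syns in entries:
            s = entity_score(node.label, (surf, *syns))
            if best is None or s > best[0] or (s == best[0] and tid < best[1]):
                best = (s, tid)
        if best is not None and best[0] >= threshold:
            links.append(TerminologyLink(node.id, best[1], "sameAs", best[0]))
    g.terminology_links = links
    return links


def to_ntriples(g: PatientGraph, base: str = "http://example.org/emr/") -> str:
    """Export the data graph, typing relation and terminology links as N-Triples."""
    from rdflib import Graph as RDFGraph, Literal, Namespace, RDF, URIRef
    from rdflib.namespace import OWL, RDFS

    ns = Namespace(base)
    rg = RDFGraph()

    def uri(s: str) -> URIRef:
        return ns[s.replace(" ", "_")]

    for n in g.data.nodes.values():
        rg.add((uri(n.id), RDF.type, uri(n.cls)))
        rg.add((uri(n.id), RDFS.label, Literal(n.label)))
        for k, v in n.attrs.items():
            rg.add((uri(n.id), uri(k), Literal(v)))
    for e in g.data.edges:
        rg.add((uri(e.source), uri(e.predicate), uri(e.target)))
    for link in g.terminology_links:
        pred = OWL.sameAs if link.kind == "sameAs" else OWL.equivalentClass
        rg.add((uri(link.entity_id), pred, uri("term/" + link.term_id)))
    return rg.serialize(format="nt")
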