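"""End-to-end question answering: segmentation -> linking -> parsing ->
semantic construction -> disambiguation -> execution."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .concepts import ConceptType
from .config import DEFAULT_CONFIG, PipelineConfig
from .cypher import to_cypher
from .engine import (ResultSet, StatisticTypeError, UnsupportedOperationError,
                     execute)
from .grammar import Grammar, coordination_rewrite, default_grammar, parse
from .kg_store import PatientGraph
from .linking import TypedSequence, annotate
from .segmentation import Lexicon, normalize_time, segment
from .semantics import (SemanticTree, UnanswerableError, attach_time, build,
                        disambiguate, serialize, tree_census)


@dataclass
class Answer:
    """Pipeline outcome: the result set plus stage-by-stage diagnostics."""

    covered: bool
    result: Optional[ResultSet] = None
    stage: Optional[str] = None      # failing stage when not covered
    category: Optional[str] = None   # vocabulary | semantics | unsupported operation
                                     # | missing schema property
    diagnostics: dict = field(default_factory=dict)


class Pipeline:
    """A question-answering session over one graph + lexicon."""

    def __init__(self, graph: PatientGraph, lexicon: Lexicon,
                 config: PipelineConfig = DEFAULT_CONFIG,
                 grammar: Grammar | None = None):
        self.graph = graph
        self.lexicon = lexicon
        self.cfg = config
        self.grammar = grammar or default_grammar()

    # -- helpers -------------------------------------------------------------

    #: types that may open a condition chunk (a logical operator kept after
    #: dropping an unknown conjunct must be followed by one of these)
    _CONDITION_OPENERS = {ConceptType.RELATION, ConceptType.NOT,
                          ConceptType.INSTANCE, ConceptType.PROPERTY,
                          ConceptType.TIME_VALUE, ConceptType.NUMBER,
                          ConceptType.ENUM_VALUE}

    def _strip_unknown(self, seq: TypedSequence) -> TypedSequence:
        kept = [t for t in seq.tokens if not t.annotation.unknown]
        out = []
        for i, t in enumerate(kept):
            if t.concept_type is ConceptType.LOGICAL_OPERATOR:
                nxt = kept[i + 1] if i + 1 < len(kept) else None
                if nxt is None or nxt.concept_type not in self._CONDITION_OPENERS:
                    continue  # conjunct vanished with its unknown token
            out.append(t)
        return TypedSequence(out, has_unknown=False)

    def interpret(self, question: str) -> tuple[Optional[SemanticTree], Answer]:
        """Run everything up to (and including) disambiguation."""
        cfg = self.cfg
        diag: dict = {}
        norm, flagged = normalize_time(question, return_flags=True)
        if flagged:
            diag["flagged_dates"] = flagged
        segres = segment(norm, self.lexicon, mode="full", cap=cfg.full_mode_cap)
        diag["accuracy_segmentation"] = [t.text for t in segres.accuracy]
        diag["n_segmentations"] = len(segres.full)
        seqs = annotate(segres, self.lexicon, self.graph.schema,
                        k=cfg.top_k, floor=cfg.sim_floor)
        diag["typed_sequences"] = [s.types for s in seqs]
        if cfg.strict:
            usable = [s for s in seqs if not s.has_unknown]
        else:
            usable = [self._strip_unknown(s) for s in seqs]
            usable = [s for s in usable if len(s)]
        if not usable:
            return None, Answer(False, stage="vocabulary", category="vocabulary",
                                diagnostics=diag)
        parsed = [(s, parse(s, self.grammar, cap=cfg.forest_cap)) for s in usable]
        parsed = [(s, f) for s, f in parsed if f]
        if not parsed:
            rewritten = [r for s in usable for r in coordination_rewrite(s)]
            diag["coordination_rewrites"] = len(rewritten)
            parsed = [(s, parse(s, self.grammar, cap=cfg.forest_cap))
                      for s in rewritten]
            parsed = [(s, f) for s, f in parsed if f]
        if not parsed:
            return None, Answer(False, stage="parse", category="semantics",
                                diagnostics=diag)
        candidates: list[SemanticTree] = []
        for s, forest in parsed:
            candidates.extend(attach_time(t, self.graph.schema)
                              for t in build(forest, self.graph.schema, s, cfg))
        if not candidates:
            return None, Answer(False, stage="disambiguation",
                                category="missing schema property", diagnostics=diag)
        tree = disambiguate(candidates, self.graph.schema)
        diag["n_candidates"] = len(candidates)
        diag["serialized"] = serialize(tree)
        diag["census"] = tree_census(tree)
        return tree, Answer(True, diagnostics=diag)

    def ask(self, question: str) -> Answer:
        """Full pipeline run; never raises for uncovered questions."""
        tree, answer = self.interpret(question)
        if tree is None:
            return answer
        try:
            answer.diagnostics["cypher"] = to_cypher(tree, self.graph.schema)
        except UnsupportedOperationError as exc:
            answer.diagnostics["cypher"] = None
            answer.diagnostics["cypher_note"] = str(exc)
        try:
            answer.result = execute(tree, self.graph, self.cfg)
        except (StatisticTypeError, UnsupportedOperationError) as exc:
            return Answer(False, stage="execution", category="unsupported operation",
                          diagnostics={**answer.diagnostics, "error": str(exc)})
        except UnanswerableError as exc:
            return Answer(False, stage="disambiguation", category="semantics",
                          diagnostics={**answer.diagnostics, "error": str(exc)})
        return answer
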