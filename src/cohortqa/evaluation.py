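"""Coverage / precision evaluation over question sets.

coverage  = answered questions / all questions
precision = correctly answered questions / answered questions

Precision requires gold answers; "correct" means exact match for counts,
lists and distributions and relative tolerance 1e-9 for sum/avg/ratio.
Unanswered questions are categorized after the uncovered-question
taxonomy: vocabulary, semantics, unsupported operation, missing schema
property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .engine import ResultSet, results_equal
from .pipeline import Pipeline


@dataclass
class QuestionStatus:
    question: str
    answered: bool
    correct: Optional[bool] = None  # None when no gold answer is available
    category: Optional[str] = None  # failure category when unanswered
    result: Optional[ResultSet] = None


@dataclass
class EvaluationReport:
    total: int
    answered: int
    correct: Optional[int]
    coverage: float
    precision: Optional[float]  # None (undefined) when answered == 0 or no gold
    per_question: list[QuestionStatus] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "total": self.total, "answered": self.answered, "correct": self.correct,
            "coverage": self.coverage, "precision": self.precision,
            "per_question": [{
                "question": s.question, "answered": s.answered,
                "correct": s.correct, "category": s.category,
            } for s in self.per_question],
        }, ensure_ascii=False, indent=2, sort_keys=True)


def evaluate(questions: Sequence[str], pipeline: Pipeline,
             gold: Sequence[ResultSet] | None = None) -> EvaluationReport:
    if not questions:
        raise ValueError("empty question set")
    if gold is not None and len(gold) != len(questions):
        raise ValueError("gold answers do not align with questions")
    statuses: list[QuestionStatus] = []
    for i, q in enumerate(questions):
        ans = pipeline.ask(q)
        if not ans.covered:
            statuses.append(QuestionStatus(q, False, category=ans.category))
            continue
        correct = None
        if gold is not None:
            correct = results_equal(ans.result, gold[i])
        statuses.append(QuestionStatus(q, True, correct=correct, result=ans.result))
    answered = sum(1 for s in statuses if s.answered)
    correct_n = None
    precision = None
    if gold is not None:
        correct_n = sum(1 for s in statuses if s.correct)
        precision = correct_n / answered if answered else None
    return EvaluationReport(
        total=len(questions), answered=answered, correct=correct_n,
        coverage=answered / len(questions), precision=precision,
        per_question=statuses)


def load_questions(path) -> tuple[list[str], Optional[list[ResultSet]]]:
    """Question file: one question per line; optional gold answer after a tab
    as JSON {"type": ..., "payload": ...}."""
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty question file")
    questions: list[str] = []
    gold: list[ResultSet] = []
    has_gold = False
    for ln in lines:
        if "\t" in ln:
            q, payload = ln.split("\t", 1)
            d = json.loads(payload)
            gold.append(ResultSet(d["type"], d.get("payload"),
                                  d.get("excluded", 0), d.get("undefined", False)))
            has_gold = True
        else:
            q = ln
            gold.append(None)  # type: ignore[arg-type]
        questions.append(q)
    if has_gold and any(g is None for g in gold):
        raise ValueError(f"{path}: gold answers must cover every question")
    return questions, (gold if has_gold else None)
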