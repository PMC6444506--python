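"""Chart parsing of concept-type sequences under the bundled CFG.

The grammar is deliberately ambiguous (logical coordination may group
either way); :func:`parse` therefore returns the whole forest of
derivations and disambiguation is delayed until schema evidence is
available.  Parsing is a general CYK-style chart: a derivability table
over (symbol, span) is filled bottom-up with a per-production split DP,
then trees are enumerated recursively up to a cap.

When a sequence is not derivable, :func:`coordination_rewrite` re-expands
elliptical coordination ("suffer A and B") by copying the governing
Relation (and Not) onto bare conjuncts, the same normalization the
original system recovered from dependency "cc"/"conj" arcs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources

from .concepts import ConceptType
from .linking import TypedSequence, TypedToken


@dataclass(frozen=True)
class Production:
    lhs: str
    rhs: tuple[str, ...]

    def __str__(self) -> str:
        return f"{self.lhs} -> " + " ".join(
            f"'{s}'" if s in TERMINALS else s for s in self.rhs)


TERMINALS = frozenset(ct.value for ct in ConceptType)


@dataclass
class Grammar:
    productions: list[Production]
    start: str = "S"

    @property
    def nonterminals(self) -> set[str]:
        return {p.lhs for p in self.productions}

    @property
    def terminals(self) -> set[str]:
        return {s for p in self.productions for s in p.rhs if s in TERMINALS}

    def validate(self) -> None:
        nts = self.nonterminals
        if self.start not in nts:
            raise ValueError(f"start symbol {self.start!r} has no production")
        for p in self.productions:
            for s in p.rhs:
                if s not in nts and s not in TERMINALS:
                    raise ValueError(f"unknown symbol {s!r} in {p}")

    @classmethod
    def from_text(cls, text: str, start: str = "S") -> "Grammar":
        prods: list[Production] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lhs, rhs_text = (part.strip() for part in line.split("->", 1))
            for alt in rhs_text.split("|"):
                symbols = tuple(s.strip("'") for s in re.findall(r"'[^']+'|\S+", alt.strip()))
                if not symbols:
                    raise ValueError(f"empty alternative in {line!r}")
                prods.append(Production(lhs, symbols))
        g = cls(prods, start)
        g.validate()
        return g

    @classmethod
    def load(cls, path=None) -> "Grammar":
        """Load from a grammar file; default is the bundled asset."""
        if path is None:
            text = resources.files("cohortqa.assets").joinpath("grammar.cfg").read_text("utf-8")
        else:
            text = open(path, encoding="utf-8").read()
        return cls.from_text(text)


_DEFAULT: Grammar | None = None


def default_grammar() -> Grammar:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Grammar.load()
    return _DEFAULT


# ---------------------------------------------------------------------------
# chart parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParseTree:
    """Internal nodes are (production, children); leaves carry the token index."""
    symbol: str
    children: tuple["ParseTree", ...] = ()
    production: Production | None = None
    leaf_index: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_index is not None

    def yield_indices(self) -> list[int]:
        if self.is_leaf:
            return [self.leaf_index]
        out: list[int] = []
        for c in self.children:
            out.extend(c.yield_indices())
        return out

    def yield_types(self) -> list[str]:
        if self.is_leaf:
            return [self.symbol]
        out: list[str] = []
        for c in self.children:
            out.extend(c.yield_types())
        return out


@dataclass
class ParseForest:
    trees: list[ParseTree]
    truncated: bool = False

    def __bool__(self) -> bool:
        return bool(self.trees)

    def __len__(self) -> int:
        return len(self.trees)


def _derivable(seq: list[str], grammar: Grammar) -> dict[tuple[str, int, int], bool]:
    """Bottom-up derivability over spans [i, j)."""
    n = len(seq)
    table: dict[tuple[str, int, int], bool] = {}
    for i, t in enumerate(seq):
        table[(t, i, i + 1)] = True

    def spans_for(symbols: tuple[str, ...], i: int, j: int) -> bool:
        # can symbols derive seq[i:j]?  DP over split points
        if not symbols:
            return i == j
        head, rest = symbols[0], symbols[1:]
        if not rest:
            return table.get((head, i, j), False)
        for k in range(i + 1, j - len(rest) + 1):
            if table.get((head, i, k), False) and spans_for(rest, k, j):
                return True
        return False

    for length in range(1, n + 1):
        for i in range(n - length + 1):
            j = i + length
            changed = True
            while changed:  # unit productions may chain (Condition -> RelationCondition)
                changed = False
                for p in grammar.productions:
                    if table.get((p.lhs, i, j), False):
                        continue
                    if len(p.rhs) <= length and spans_for(p.rhs, i, j):
                        table[(p.lhs, i, j)] = True
                        changed = True
    return table


def recognizes(seq: list[str], grammar: Grammar | None = None) -> bool:
    """Chart recognizer: does the start symbol derive the sequence?"""
    grammar = grammar or default_grammar()
    if not seq:
        raise ValueError("empty sequence")
    return _derivable(list(seq), grammar).get((grammar.start, 0, len(seq)), False)


def parse(seq: TypedSequence | list[str], grammar: Grammar | None = None,
          cap: int = 256) -> ParseForest:
    """Every distinct derivation of the sequence from S, up to ``cap``."""
    grammar = grammar or default_grammar()
    types = seq.types if isinstance(seq, TypedSequence) else list(seq)
    if not types:
        raise ValueError("empty sequence")
    table = _derivable(types, grammar)
    truncated = False

    def trees(symbol: str, i: int, j: int, budget: int,
              seen: frozenset) -> list[ParseTree]:
        nonlocal truncated
        out: list[ParseTree] = []
        if j - i == 1 and symbol == types[i]:
            out.append(ParseTree(symbol, leaf_index=i))
        key = (symbol, i, j)
        if key in seen:  # block unit-production cycles
            return out
        seen = seen | {key}
        for p in grammar.productions:
            if p.lhs != symbol or not table.get((symbol, i, j), False):
                continue
            for split in _splits(p.rhs, i, j):
                combos: list[list[ParseTree]] = [[]]
                for (sym, a, b) in split:
                    subtrees = trees(sym, a, b, budget, seen if len(p.rhs) == 1 else frozenset())
                    new_combos = []
                    for c in combos:
                        for st in subtrees:
                            new_combos.append(c + [st])
                            if len(new_combos) > budget:
                                truncated = True
                                break
                        if len(new_combos) > budget:
                            break
                    combos = new_combos
                for c in combos:
                    out.append(ParseTree(symbol, tuple(c), production=p))
                    if len(out) > budget:
                        truncated = True
                        return out[:budget]
        return out

    def _splits(symbols: tuple[str, ...], i: int, j: int):
        if len(symbols) == 1:
            if table.get((symbols[0], i, j), False):
                yield [(symbols[0], i, j)]
            return
        head, rest = symbols[0], symbols[1:]
        for k in range(i + 1, j - len(rest) + 1):
            if table.get((head, i, k), False):
                for tail in _splits(rest, k, j):
                    yield [(head, i, k)] + tail

    if not table.get((grammar.start, 0, len(types)), False):
        return ParseForest([], False)
    all_trees = trees(grammar.start, 0, len(types), cap, frozenset())
    return ParseForest(all_trees[:cap], truncated or len(all_trees) > cap)


# ---------------------------------------------------------------------------
# coordination rewrite (the dependency-parser fallback, as a pure transform)
# ---------------------------------------------------------------------------

def coordination_rewrite(seq: TypedSequence) -> list[TypedSequence]:
    """Copy the governing Relation onto bare conjuncts.

    ``Relation Instance LogicalOperator [Not] Instance`` becomes
    ``Relation Instance LogicalOperator [Not] Relation Instance``,
    applied left-to-right to a fixpoint so conjunct chains are covered.
    Returns the rewritten sequence (strictly longer than the input) or an
    empty list when no pattern applies.
    """
    tokens = list(seq.tokens)
    changed = False
    i = 0
    while i < len(tokens):
        if tokens[i].concept_type is ConceptType.LOGICAL_OPERATOR:
            j = i + 1
            if j < len(tokens) and tokens[j].concept_type is ConceptType.NOT:
                j += 1
            if j < len(tokens) and tokens[j].concept_type is ConceptType.INSTANCE:
                governing = None
                for t in reversed(tokens[:i]):
                    if t.concept_type is ConceptType.RELATION:
                        governing = t
                        break
                if governing is not None:
                    copy = TypedToken(ConceptType.RELATION,
                                      replace(governing.annotation, synthetic=True))
                    tokens.insert(j, copy)
                    changed = True
                    i = j + 1
                    continue
        i += 1
    if not changed:
        return []
    return [TypedSequence(tokens, seq.has_unknown)]
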