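"""Lexicon, time normalization and dual-mode dictionary segmentation.

Questions arrive either whitespace-delimited (Latin script) or
unsegmented (CJK).  Both are reduced to a list of atomic *units*
(whitespace tokens, or single characters with digit runs kept whole) and
tokenized against the medical lexicon:

* accuracy mode — greedy longest dictionary match, one token list;
* full mode — every tokenization in which each token is a dictionary
  word, a number or a canonical date; positions where no dictionary word
  starts contribute a single "unknown" unit.  Both modes are passed
  downstream, mirroring the dual segmenter modes of the original
  pipeline; grammar and schema evidence pick the winner later.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .concepts import CLOSED_TYPES, CONTENT_TYPES, ConceptType

#: auxiliary lexicon-row kinds that are not concept entries
AUX_TYPES = ("Word", "Stopword")

_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")
_DATE_RE = re.compile(r"^\d{8}$")
_PUNCT_RE = re.compile(r"[?？!！。．，,;；:：]")


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    """One surface form mapped to a typed canonical concept.

    ``cls`` carries the ontology class of instance entries (needed for
    schema disambiguation) or the owner attribute of unit entries.
    """

    surface: str
    canonical_id: str
    concept_type: ConceptType
    synonyms: tuple[str, ...] = ()
    cls: str | None = None
    display: str | None = None  # canonical display label (defaults to surface)

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty surface form")

    @property
    def display_label(self) -> str:
        return self.display or self.surface

    @property
    def all_surfaces(self) -> tuple[str, ...]:
        return (self.surface, *self.synonyms)


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    #: segmentation-dictionary-only words (no concept binding)
    extra_words: set[str] = field(default_factory=set)
    stopwords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index: dict[str, list[LexiconEntry]] = {}
        for e in self.entries:
            for s in e.all_surfaces:
                self._index.setdefault(s, []).append(e)

    def add(self, entry: LexiconEntry) -> None:
        self.entries.append(entry)
        for s in entry.all_surfaces:
            self._index.setdefault(s, []).append(entry)

    def words(self) -> set[str]:
        """All dictionary words usable by the segmenter."""
        return set(self._index) | self.extra_words | self.stopwords

    def exact(self, surface: str) -> list[LexiconEntry]:
        return self._index.get(surface, [])

    def closed_matches(self, surface: str) -> list[LexiconEntry]:
        return [e for e in self.exact(surface) if e.concept_type in CLOSED_TYPES]

    def content_entries(self) -> list[LexiconEntry]:
        return [e for e in self.entries if e.concept_type in CONTENT_TYPES]

    # --- TSV round trip ----------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        """Columns: surface, canonical_id, concept_type, synonyms (|-sep), cls.

        Rows typed ``Word`` feed only the segmentation dictionary; rows
        typed ``Stopword`` are dropped at annotation time.
        """
        lex = cls()
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno + 1}: expected >= 3 tab-separated columns")
            surface, canonical, ctype = parts[0], parts[1], parts[2]
            if ctype == "Word":
                lex.extra_words.add(surface)
                continue
            if ctype == "Stopword":
                lex.stopwords.add(surface)
                continue
            syns = tuple(s for s in parts[3].split("|") if s) if len(parts) > 3 else ()
            owner = parts[4] if len(parts) > 4 and parts[4] else None
            display = parts[5] if len(parts) > 5 and parts[5] else None
            lex.add(LexiconEntry(surface, canonical, ConceptType(ctype), syns,
                                 owner, display))
        return lex

    def to_tsv(self, path) -> None:
        lines = []
        for e in self.entries:
            lines.append("\t".join([e.surface, e.canonical_id, e.concept_type.value,
                                    "|".join(e.synonyms), e.cls or "",
                                    e.display or ""]))
        for w in sorted(self.extra_words):
            lines.append(f"{w}\t\tWord\t\t")
        for w in sorted(self.stopwords):
            lines.append(f"{w}\t\tStopword\t\t")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def core_lexicon(script: str = "en") -> Lexicon:
    """The bundled closed-class core lexicon ('en' or 'zh')."""
    from importlib import resources
    ref = resources.files("cohortqa.assets").joinpath(f"core_{script}.tsv")
    with resources.as_file(ref) as path:
        return Lexicon.from_tsv(path)


def zh_label_map() -> dict[str, tuple[str, ...]]:
    """Chinese surface forms of the bundled catalog entity labels."""
    from importlib import resources
    text = resources.files("cohortqa.assets").joinpath("zh_labels.tsv").read_text("utf-8")
    out: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, surfaces = line.split("\t")
        out[label] = tuple(surfaces.split("|"))
    return out


def lexicon_from_graph(g, core: Lexicon,
                       label_map: dict[str, tuple[str, ...]] | None = None) -> Lexicon:
    """Derive the question lexicon from a patient graph.

    Combines the bundled closed-class core (operators, units, stopwords)
    with entries extracted from the schema graph (classes, predicates,
    attributes, enum values) and the data-graph catalog labels.  An
    optional ``label_map`` supplies script-specific surface forms for
    instance labels (used by the CJK lexicon).
    """
    lex = Lexicon(list(core.entries), set(core.extra_words), set(core.stopwords))
    known = {(e.surface, e.concept_type) for e in lex.entries}

    def add(surface, canonical, ctype, syns=(), cls=None):
        if (surface, ctype) not in known:
            lex.add(LexiconEntry(surface, canonical, ctype, tuple(syns), cls))
            known.add((surface, ctype))

    gs = g.schema
    for c in sorted(gs.classes):
        add(c, c, ConceptType.CLASS)
    by_pred: dict[str, list[str]] = {}
    for surf, canon in gs.predicate_synonyms.items():
        by_pred.setdefault(canon, []).append(surf)
    for rec in gs.predicates:
        if rec.range in gs.classes:
            add(rec.name, rec.name, ConceptType.RELATION,
                syns=sorted(by_pred.get(rec.name, [])))
    for attr in gs.attributes.values():
        add(attr.name, attr.name, ConceptType.PROPERTY, cls=attr.owner)
        for v in attr.enum_values:
            add(v, v, ConceptType.ENUM_VALUE, cls=attr.name)
        for u in attr.units:
            add(u, attr.name, ConceptType.UNIT, cls=attr.name)
    for node in sorted(g.data.nodes.values(), key=lambda n: n.id):
        if node.cls == "patient" or node.label == node.cls:
            continue
        if label_map and node.label in label_map:
            surfaces = label_map[node.label]
            if (surfaces[0], ConceptType.INSTANCE) not in known:
                lex.add(LexiconEntry(surfaces[0], node.id, ConceptType.INSTANCE,
                                     (*surfaces[1:], node.label), node.cls,
                                     display=node.label))
                known.add((surfaces[0], ConceptType.INSTANCE))
        else:
            add(node.label, node.id, ConceptType.INSTANCE, cls=node.cls)
    return lex


# ---------------------------------------------------------------------------
# time normalization
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"(\d{4})(?:年|/|-)(\d{1,2})(?:月|/|-)(\d{1,2})日?")


def normalize_time(question: str, return_flags: bool = False):
    """Replace date expressions with canonical 8-digit yyyymmdd tokens.

    The three supported dialects (2015/6/10, 2015-6-10, 2015年6月10日)
    all map to the same token.  Out-of-range months/days are left
    unmodified and flagged.
    """
    flagged: list[str] = []

    def repl(m: re.Match) -> str:
        y, mo, d = int(m.group(1)), int(m.group(2)), int(m.group(3))
        if not (1 <= mo <= 12 and 1 <= d <= 31):
            flagged.append(m.group(0))
            return m.group(0)
        return f"{y:04d}{mo:02d}{d:02d}"

    out = _TIME_RE.sub(repl, question)
    return (out, flagged) if return_flags else out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    text: str
    source: str  # 'lexicon' | 'number' | 'date' | 'unknown'


@dataclass
class SegmentationResult:
    accuracy: list[Token]
    full: list[list[Token]]
    truncated: bool = False
    joiner: str = ""


def _units(text: str) -> tuple[list[str], str]:
    """Atomic units and the joiner used to rebuild multi-unit words."""
    stripped = _PUNCT_RE.sub(" ", text)
    if re.search(r"\s", stripped.strip()):
        return stripped.split(), " "
    units: list[str] = []
    for m in re.finditer(r"\d+(?:\.\d+)?|\S", stripped):
        units.append(m.group(0))
    return units, ""


def _classify(word: str, in_dict: bool) -> str:
    if _DATE_RE.match(word):
        return "date"
    if _NUMBER_RE.match(word):
        return "number"
    return "lexicon" if in_dict else "unknown"


def segment(question: str, lexicon: Lexicon, mode: str = "full",
            cap: int = 64) -> SegmentationResult:
    """Tokenize a (time-normalized) question against the lexicon."""
    if mode not in ("accuracy", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    units, joiner = _units(question)
    words = lexicon.words()
    max_units = max((len(w.split(joiner)) if joiner else len(w)) for w in words) if words else 1

    def matches_at(i: int) -> list[int]:
        """End indices j > i such that units[i:j] joins to a dictionary word."""
        out = []
        for j in range(min(len(units), i + max_units), i, -1):
            cand = joiner.join(units[i:j])
            if cand in words or _NUMBER_RE.match(cand) or _DATE_RE.match(cand):
                out.append(j)
        return out  # longest first

    # accuracy mode: greedy longest match
    acc: list[Token] = []
    i = 0
    while i < len(units):
        ends = matches_at(i)
        j = ends[0] if ends else i + 1
        word = joiner.join(units[i:j])
        acc.append(Token(word, _classify(word, bool(ends))))
        i = j

    full: list[list[Token]] = []
    truncated = False

    def enumerate_from(i: int, prefix: list[Token]) -> bool:
        """DFS, longest-first; returns False when the cap is hit."""
        nonlocal truncated
        if i == len(units):
            full.append(list(prefix))
            if len(full) >= cap:
                truncated = True
                return False
            return True
        ends = matches_at(i)
        options = [(j, True) for j in ends] if ends else [(i + 1, False)]
        for j, in_dict in options:
            word = joiner.join(units[i:j])
            prefix.append(Token(word, _classify(word, in_dict)))
            ok = enumerate_from(j, prefix)
            prefix.pop()
            if not ok:
                return False
        return True

    if mode == "full":
        enumerate_from(0, [])
    else:
        full = [acc]
    return SegmentationResult(accuracy=acc, full=full, truncated=truncated, joiner=joiner)
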