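"""Concept linking: typed annotation of tokens against the lexicon.

A token is linked to graph concepts by an averaged string similarity

    sigma(a, b) = (L + T + LCS) / 3

with L = 1 - LevenshteinDistance/max(|a|,|b|) (normalized edit
similarity), T = Jaccard overlap of character-trigram sets, and
LCS = longest-common-substring length / max(|a|,|b|).  An entity's score
is the maximum of sigma over its synonym set, and the top-k entities
become the token's candidates; disambiguation is delayed until schema
evidence is available.

Trigram convention: contiguous character 3-grams over the raw string
(spaces retained, no padding); strings shorter than 3 characters fall
back to the whole string as a single gram.  The convention is isolated
in :func:`trigrams` so it can be swapped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .concepts import ConceptType
from .kg_store import SchemaGraph
from .segmentation import Lexicon, SegmentationResult, Token

_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")
_DATE_RE = re.compile(r"^\d{8}$")


# ---------------------------------------------------------------------------
# string similarity (the linking primitive)
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance (insert/delete/substitute)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous common substring."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            v = prev[j - 1] + 1 if ca == cb else 0
            cur.append(v)
            if v > best:
                best = v
        prev = cur
    return best


def trigrams(s: str) -> frozenset[str]:
    if len(s) < 3:
        return frozenset({s})
    return frozenset(s[i:i + 3] for i in range(len(s) - 2))


def similarity(a: str, b: str) -> float:
    """Averaged similarity sigma(a, b) in [0, 1]."""
    if not a or not b:
        raise ValueError("similarity of an empty string is undefined")
    m = max(len(a), len(b))
    lev = 1.0 - levenshtein(a, b) / m
    ga, gb = trigrams(a), trigrams(b)
    tri = len(ga & gb) / len(ga | gb)
    lcs = longest_common_substring(a, b) / m
    return (lev + tri + lcs) / 3.0


def entity_score(token: str, surfaces: Sequence[str]) -> float:
    """Best sigma between a token and any of an entity's surface forms."""
    return max(similarity(token, s) for s in surfaces)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    entity_id: str
    concept_type: ConceptType
    score: float
    cls: str | None = None
    label: str | None = None  # canonical display label


@dataclass
class Annotation:
    token: str
    candidates: list[Candidate] = field(default_factory=list)
    chosen: int | None = None
    synthetic: bool = False

    @property
    def unknown(self) -> bool:
        return not self.candidates

    @property
    def top(self) -> Candidate:
        return self.candidates[0]


@dataclass
class TypedToken:
    concept_type: ConceptType
    annotation: Annotation

    @property
    def synthetic(self) -> bool:
        return self.annotation.synthetic


@dataclass
class TypedSequence:
    tokens: list[TypedToken]
    has_unknown: bool = False

    @property
    def types(self) -> list[str]:
        return [t.concept_type.value for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


def link_token(token: str, lexicon: Lexicon, k: int = 5,
               floor: float = 0.0) -> Annotation:
    """Rank content entries by entity score; keep the top k above the floor.

    Ties break lexicographically on the entity id so annotation is
    deterministic.  An exact surface/synonym match scores sigma = 1 and
    therefore always ranks first.
    """
    if not lexicon.entries:
        raise ValueError("lexicon is empty")
    scored: list[Candidate] = []
    for e in lexicon.content_entries():
        s = entity_score(token, e.all_surfaces)
        if s >= floor:
            scored.append(Candidate(e.canonical_id, e.concept_type, s, e.cls,
                                    e.display_label))
    scored.sort(key=lambda c: (-c.score, c.entity_id))
    return Annotation(token, scored[:k])


def annotate(segmentations: SegmentationResult | Iterable[Sequence[Token]],
             lexicon: Lexicon, schema: SchemaGraph, k: int = 5,
             floor: float = 0.4) -> list[TypedSequence]:
    """One (or more, after attribute supplementation) typed sequence per
    surviving segmentation.

    Numbers and dates are recognized by pattern, operators and units by
    the closed word lists of the lexicon, content tokens by similarity
    linking.  Stopwords are dropped; unknown tokens are kept but flag the
    sequence (strict mode downstream rejects it).
    """
    token_lists = segmentations.full if isinstance(segmentations, SegmentationResult) \
        else [list(t) for t in segmentations]
    out: list[TypedSequence] = []
    seen: set[tuple] = set()
    for tokens in token_lists:
        seq_tokens: list[TypedToken] = []
        has_unknown = False
        for tok in tokens:
            text = tok.text
            if text in lexicon.stopwords:
                continue
            if _DATE_RE.match(text):
                ann = Annotation(text, [Candidate(text, ConceptType.TIME_VALUE, 1.0)])
                seq_tokens.append(TypedToken(ConceptType.TIME_VALUE, ann))
                continue
            if _NUMBER_RE.match(text):
                ann = Annotation(text, [Candidate(text, ConceptType.NUMBER, 1.0)])
                seq_tokens.append(TypedToken(ConceptType.NUMBER, ann))
                continue
            closed = lexicon.closed_matches(text)
            if closed:
                cands = sorted(
                    (Candidate(e.canonical_id, e.concept_type, 1.0, e.cls,
                               e.display_label)
                     for e in closed), key=lambda c: (c.concept_type.value, c.entity_id))
                seq_tokens.append(TypedToken(cands[0].concept_type,
                                             Annotation(text, list(cands))))
                continue
            ann = link_token(text, lexicon, k=k, floor=floor)
            if ann.unknown:
                has_unknown = True
                seq_tokens.append(TypedToken(ConceptType.INSTANCE, ann))
                continue
            top_type = ann.top.concept_type
            ann.candidates = [c for c in ann.candidates if c.concept_type == top_type]
            seq_tokens.append(TypedToken(top_type, ann))
        for seq in supplement_attributes(TypedSequence(seq_tokens, has_unknown), schema):
            key = tuple((t.concept_type.value,
                         t.annotation.token,
                         t.synthetic) for t in seq.tokens)
            if key not in seen:
                seen.add(key)
                out.append(seq)
    return out


# ---------------------------------------------------------------------------
# missing-attribute supplementation
# ---------------------------------------------------------------------------

_VALUE_REGION = {ConceptType.NUMBER, ConceptType.UNIT, ConceptType.ARITHMETIC_OPERATOR,
                 ConceptType.RANGE_SEPARATOR, ConceptType.TIME_VALUE}


def _region_start(tokens: list[TypedToken], i: int) -> int:
    """Leftmost index of the contiguous value region containing index i."""
    j = i
    while j > 0 and tokens[j - 1].concept_type in _VALUE_REGION:
        j -= 1
    return j


def _has_governing_property(tokens: list[TypedToken], i: int) -> bool:
    j = _region_start(tokens, i)
    return j > 0 and tokens[j - 1].concept_type is ConceptType.PROPERTY


def _property_token(attr_name: str, owner: str) -> TypedToken:
    ann = Annotation(attr_name,
                     [Candidate(attr_name, ConceptType.PROPERTY, 1.0, owner, attr_name)],
                     synthetic=True)
    return TypedToken(ConceptType.PROPERTY, ann)


def supplement_attributes(seq: TypedSequence, schema: SchemaGraph) -> list[TypedSequence]:
    """Insert omitted Property tokens implied by units or enum values.

    A Number+Unit pair with no governing Property receives the attribute
    owning that unit ("60 years old" -> age); a bare EnumValue receives
    the attribute owning that value ("female" -> sex).  Inserted tokens
    are marked synthetic.  A unit or value owned by several attributes
    yields one alternative sequence per owner.
    """
    variants: list[list[TypedToken]] = [list(seq.tokens)]
    progressed = True
    while progressed:
        progressed = False
        next_variants: list[list[TypedToken]] = []
        for tokens in variants:
            insert_at: int | None = None
            owners: list = []
            for i, tt in enumerate(tokens):
                if tt.concept_type is ConceptType.NUMBER and i + 1 < len(tokens) \
                        and tokens[i + 1].concept_type is ConceptType.UNIT \
                        and not _has_governing_property(tokens, i):
                    unit_entry = tokens[i + 1].annotation.top
                    owners = schema.attributes_by_unit(tokens[i + 1].annotation.token) \
                        or ([schema.attribute(unit_entry.entity_id)]
                            if schema.attribute(unit_entry.entity_id) else [])
                    if owners:
                        insert_at = _region_start(tokens, i)
                        break
                if tt.concept_type is ConceptType.ENUM_VALUE \
                        and not _has_governing_property(tokens, i):
                    owners = schema.attributes_by_enum(tt.annotation.token) \
                        or schema.attributes_by_enum(tt.annotation.top.entity_id)
                    if owners:
                        insert_at = i
                        break
            if insert_at is None:
                next_variants.append(tokens)
            else:
                progressed = True
                for attr in sorted(owners, key=lambda a: a.name):
                    new = list(tokens)
                    new.insert(insert_at, _property_token(attr.name, attr.owner))
                    next_variants.append(new)
        variants = next_variants
    return [TypedSequence(v, seq.has_unknown) for v in variants]
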