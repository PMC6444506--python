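import pytest
from hypothesis import given, settings, strategies as st

from cohortqa import (Lexicon, LexiconEntry, annotate, default_schema, entity_score,
                      levenshtein, link_token, longest_common_substring, segment,
                      similarity, supplement_attributes, trigrams)
from cohortqa.concepts import ConceptType
from cohortqa.linking import Annotation, Candidate, TypedSequence, TypedToken

from conftest import SEQ_14, SEQ_16, CANONICAL_ZH


# ---------------------------------------------------------------------------
# similarity components
# ---------------------------------------------------------------------------

def test_similarity_identity_is_one():
    for x in ("glucose", "高血糖", "a"):
        assert similarity(x, x) == 1.0


def test_similarity_of_disjoint_strings_is_zero():
    assert similarity("abc", "xyz") == 0.0


def test_glucose_worked_example():
    # frozen dynamic-programming oracle values for "glucose" vs "blood glucose"
    a, b = "glucose", "blood glucose"
    assert levenshtein(a, b) == 6
    assert longest_common_substring(a, b) == 7
    assert trigrams(a) == frozenset({"glu", "luc", "uco", "cos", "ose"})
    assert len(trigrams(b)) == 11
    L = 1 - 6 / 13
    T = 5 / 11
    LCS = 7 / 13
    assert similarity(a, b) == pytest.approx((L + T + LCS) / 3)
    assert similarity(a, b) == pytest.approx(0.5104895104895105)


def test_short_strings_fall_back_to_whole_string_gram():
    assert trigrams("ab") == frozenset({"ab"})


def test_empty_string_is_a_parameter_error():
    with pytest.raises(ValueError):
        similarity("", "x")


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.text(min_size=1, max_size=12), st.text(min_size=1, max_size=12))
def test_similarity_bounded_and_symmetric(a, b):
    m = max(len(a), len(b))
    assert 0 <= 1 - levenshtein(a, b) / m <= 1
    assert 0 <= longest_common_substring(a, b) / m <= 1
    s = similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(similarity(b, a))


# ---------------------------------------------------------------------------
# link_token
# ---------------------------------------------------------------------------

def _content_lexicon(surfaces):
    return Lexicon([LexiconEntry(s, f"e{i:02d}", ConceptType.INSTANCE)
                    for i, s in enumerate(surfaces)])


def test_glucose_links_to_both_test_and_drug_candidates():
    lex = _content_lexicon(["blood glucose", "glucose oral liquid", "warfarin"])
    ann = link_token("glucose", lex, k=5, floor=0.2)
    labels = [c.label for c in ann.candidates[:2]]
    assert set(labels) == {"blood glucose", "glucose oral liquid"}


def test_exact_surface_match_ranks_first_with_score_one():
    lex = _content_lexicon(["captopril", "captopril tablet"])
    ann = link_token("captopril", lex, k=3)
    assert ann.top.label == "captopril" and ann.top.score == 1.0


def test_tie_breaks_on_lexicographic_entity_id():
    lex = Lexicon([LexiconEntry("aaa", "z9", ConceptType.INSTANCE),
                   LexiconEntry("aaa", "a1", ConceptType.INSTANCE)])
    ann = link_token("aaa", lex, k=1)
    assert ann.top.entity_id == "a1"


def test_link_token_with_full_k_is_sorted_like_brute_force():
    surfaces = ["blood glucose", "glucose oral liquid", "hypertension",
                "hyperglycemia", "captopril"]
    lex = _content_lexicon(surfaces)
    ann = link_token("glucose", lex, k=len(surfaces), floor=0.0)
    expected = sorted(((entity_score("glucose", (s,)), f"e{i:02d}")
                       for i, s in enumerate(surfaces)),
                      key=lambda t: (-t[0], t[1]))
    assert [(c.score, c.entity_id) for c in ann.candidates] == \
        [(pytest.approx(s), e) for s, e in expected]


# ---------------------------------------------------------------------------
# annotation of the canonical question
# ---------------------------------------------------------------------------

def test_canonical_question_gets_both_printed_sequences(fg, zh_lexicon):
    res = segment(CANONICAL_ZH.rstrip("?"), zh_lexicon)
    seqs = annotate(res, zh_lexicon, fg.schema)
    types = [s.types for s in seqs]
    assert SEQ_14 in types
    assert SEQ_16 in types
    # the accuracy-mode segmentation yields the 14-type sequence
    acc = annotate([res.accuracy], zh_lexicon, fg.schema)
    assert acc[0].types == SEQ_14


@pytest.mark.parametrize("token, expected", [
    ("30.96", "Number"), ("20170909", "TimeValue")])
def test_pattern_tokens(fg, zh_lexicon, token, expected):
    from cohortqa.segmentation import Token
    seqs = annotate([[Token(token, "unknown")]], zh_lexicon, fg.schema)
    assert seqs[0].types == [expected]


# ---------------------------------------------------------------------------
# attribute supplementation
# ---------------------------------------------------------------------------

def _tok(ctype, text, entity=None, cls=None):
    ann = Annotation(text, [Candidate(entity or text, ctype, 1.0, cls, text)])
    return TypedToken(ctype, ann)


def test_number_unit_pair_gets_age_property():
    schema = default_schema()
    seq = TypedSequence([_tok(ConceptType.NUMBER, "60"),
                         _tok(ConceptType.UNIT, "years old", entity="age", cls="age"),
                         _tok(ConceptType.CLASS, "patient")])
    out = supplement_attributes(seq, schema)
    assert len(out) == 1
    assert out[0].types == ["Property", "Number", "Unit", "Class"]
    assert out[0].tokens[0].annotation.token == "age"
    assert out[0].tokens[0].synthetic


def test_bare_enum_value_gets_sex_property():
    schema = default_schema()
    seq = TypedSequence([_tok(ConceptType.ENUM_VALUE, "female", cls="sex"),
                         _tok(ConceptType.CLASS, "patient")])
    out = supplement_attributes(seq, schema)
    assert out[0].types == ["Property", "EnumValue", "Class"]
    assert out[0].tokens[0].annotation.token == "sex"


def test_explicit_property_is_untouched_and_idempotent():
    schema = default_schema()
    seq = TypedSequence([
        _tok(ConceptType.PROPERTY, "age", cls="patient"),
        _tok(ConceptType.ARITHMETIC_OPERATOR, "over", entity="gt"),
        _tok(ConceptType.NUMBER, "60"),
        _tok(ConceptType.UNIT, "years old", entity="age", cls="age"),
    ])
    out = supplement_attributes(seq, schema)
    assert len(out) == 1 and out[0].types == seq.types
    again = supplement_attributes(out[0], schema)
    assert again[0].types == out[0].types
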