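# Methods

This note documents the models, conventions and design decisions behind
`cohortqa`, in the order the pipeline applies them.

## Data model

The patient graph is G = ⟨Gs, Gd, R⟩.  The bundled schema
(`default_schema()`) has six classes — patient, disease, drug, test,
procedure, hospitalization — and five event predicates with
patient-side domains: `suffer` (→disease), `take` (→drug), `have test`
(→test), `operate` (→procedure), `in hospital` (→hospitalization).
Attribute predicates (`sex`, `age`, `birthday`) range over datatypes.
The attribute registry records each attribute's owner class, value kind
(numeric / enum / date / text), unit names and enum values; units and
enum values are unique keys across the registry because missing-attribute
supplementation inverts them ("years old" → age, "female" → sex).

Two storage conventions matter downstream:

* **Timestamps live on event edges**, as canonical `yyyymmdd` integers,
  so chronological comparisons ("took drugs *after* the diagnosis") are
  edge-local.  A missing date is an explicit `None` and is excluded from
  every time-filtered match — silently including undated events would
  corrupt "after" semantics.
* **Event-level measurements live on edges too** (`result` enum and
  `value` numeric on test edges, `value` = stay days on admissions),
  because catalog nodes like "blood glucose" are shared by all patients.
  A condition pair such as ⟨patient, have test, blood glucose⟩
  ⟨blood glucose, test result, low⟩ is therefore stored as one event
  triple with an edge constraint; it serializes and is counted in the
  census as the two drawn triples.

The store is in-memory only; Cypher is an output dialect.  N-Triples
export (rdf:type for R, owl:sameAs for terminology links) is provided
for RDF interoperability.

## String similarity and linking

σ = (L + T + LCS)/3 with L the normalized Levenshtein similarity, T the
Jaccard overlap of character trigram sets and LCS the normalized longest
common substring.  Trigrams are contiguous character 3-grams over the
raw string, spaces retained, no padding; strings shorter than three
characters fall back to the whole string as a single gram.  The
convention is isolated in `trigrams()` so it can be swapped.

An entity's score against a token is the maximum σ over its synonym
set; the top *k* = 5 entities become candidates, tokens whose best score
falls below the floor 0.4 are "unknown".  Ties break by entity id so
annotation is deterministic.  The terminology sameAs threshold defaults
to 0.75; the value is normally tuned per deployment on an annotated
linking sample, so it is exposed in `PipelineConfig` rather than fixed.

## Segmentation

Both scripts reduce to atomic units — whitespace tokens for Latin text
(multi-word lexicon entries are re-merged), single characters with
digit runs kept whole for unsegmented text.  Accuracy mode is greedy
longest dictionary match; full mode enumerates every tokenization whose
tokens are dictionary words, numbers or 8-digit dates, capped at 64
alternatives.  Unknown units are *fallback-only*: they appear exactly at
positions where no dictionary word starts.  Allowing them anywhere would
make every question exponentially ambiguous while adding no reading the
downstream stages could use; the restriction preserves the dictionary
ambiguity that motivates full mode (女患者 vs 女/患者) and is mirrored
by the brute-force enumeration oracle in the tests.  Unknown tokens are
kept, not dropped: strict mode (default) rejects a question containing
one, lenient mode answers the reduced question (and prunes a logical
operator whose conjunct vanished with the unknown token) — the lenient
behaviour exists because silently ignoring entities is a documented
error source, and strict mode makes it visible instead.

Time normalization maps the three supported dialects — `2015/6/10`,
`2015-6-10`, `2015年6月10日` — to one canonical `20150610` token before
segmentation; out-of-range dates are left intact and flagged.

## Grammar and parsing

The grammar over the 14 concept-type terminals ships as a declarative
asset (`assets/grammar.cfg`, one production per line) so coverage can be
extended by editing a file rather than code.  One production was added
beyond the core table: `QueryItem -> 'StatisticOperator'`, because count
queries routinely end in a bare statistic word ("…患者数量") with no
target property — without it the running demonstration question itself
is underivable.

Parsing is a general CYK-style chart (bottom-up derivability table over
spans with a per-production split DP, then recursive tree enumeration).
The grammar is genuinely ambiguous — `Condition → Condition
LogicalOperator Condition` admits both associations — so the full forest
(capped at 256 derivations) is kept and disambiguation is deferred.
When no sequence derives S, the coordination rewrite copies the
governing Relation (and Not) onto bare conjuncts
(`R I LogicalOperator [Not] I` → `R I LogicalOperator [Not] R I`),
iterated left-to-right; each application strictly lengthens the
sequence, so it terminates.  This is a pure sequence transformation —
no dependency parser is embedded.

## Semantic trees

Relation chunks become event triples whose subject comes from the
predicate's schema domain; when the question carries a trailing Class
token it binds as the subject of all condition triples lacking one, and
the patient class is the default (questions habitually leave "patient"
implicit).  Property chunks become node-attribute triples when the
attribute belongs to the subject class, and edge-constrained event
triples (with an automatically inserted anchor predicate) when it
belongs to an event class.  Precedence is Not > LogicalOperator >
TimeOperator, with Not always wrapping a single triple.

**Disambiguation** scores each candidate tree by (number of
schema-realizable triple parts, summed linking σ) and keeps the
maximum; remaining ties break on the lexicographically smallest
canonical serialization, which prefers the left-associated logical
structure.  Candidates containing a chunk with no schema-compatible
reading are dropped during construction.

**Chronology.**  The serialization reads `A after B` as a sequencing
connective: A's events precede B's (the reading of the postposition 后
that the canonical expressions gloss as "after", and the one consistent
with "heart failure after coronary heart disease" meaning the failure
came first).  Executor, oracle and Cypher emitter all implement
"after" as *left witness strictly earlier*; same-day events satisfy
neither direction.  Time joins are created only from explicit
TimeOperator tokens, with one schema-driven extension: event predicates
carry a chronology rank in the schema (diagnoses 0, admissions 1,
treatments 2, tests 3), and an explicit chain absorbs the contiguous run
of immediately preceding sibling relation conditions whose ranks all lie
strictly below the chain head's (diagnoses stated before "took drugs
after…" join the chain as its earliest link).  No join is ever invented
in a question with no time operator; hidden chronology beyond this rule
is a known limitation.

**Census.**  `tree_census` counts nodes as the distinct subjects,
objects and values plus the query placeholder, and edges as triple
predicates (query edge included) plus one per time join — the convention
under which the canonical demonstration tree has 8 nodes and 9 edges.

The canonical serialization (`<s, p, o>` triples, `(not …)`, group
parentheses, adjacency = And, operator words for time joins, query item
last, `@lo-hi` suffixes for edge date filters) parses back via
`parse_serialized`; round-tripping is the identity on the serialized
form.

## Execution semantics

A patient satisfies a positive event triple iff a matching edge exists
(object, edge-value and date filters included); a negated triple iff no
matching edge exists; And/Or intersect/unite satisfying sets.  A time
join holds iff some *witness assignment* — one timestamped edge per
positive event triple in the join, Or-branches expanded into alternative
conjunctive scenarios first — satisfies every ordering pair; multiple
qualifying edges are existential (any witness pair suffices).  The
indexed executor and the deliberately naive per-patient oracle implement
this contract independently and are compared on hundreds of random
tree × graph cases.

Statistics: count = |cohort|; list = cohort rows (or related-entity
labels); sum/avg over the numeric target, with members missing the
attribute excluded and reported; distribution = counts grouped by the
target value, numeric values binned (age: width 10 anchored at 0,
otherwise 10 equal-width bins over the observed range — both
configurable); ratio = |cohort ∩ numerator| / |cohort|, where the
numerator is the last relation-condition chunk before the statistic
word and an empty cohort yields an explicit *undefined*, never 0.
Averaging a non-numeric property is a type error, surfaced as an
"unsupported operation" outcome.

Cypher output (Neo4j 3.x dialect: pattern predicates in WHERE,
`count()`/`collect()`-style aggregates) is deterministic text with
variables numbered in traversal order; it is never executed here.  A
time join over a disjunctive operand has no conjunctive edge variable
and raises an unsupported-operation error in the emitter (the native
executor still answers via scenario expansion); grouped sort / top-N
and growth-rate statistics are out of scope.

## Synthetic data

The generator emulates a heart-failure repository's shape scaled to desk
size: per-patient Poisson event counts ordered like the source data
(drug exposures ≈ 6 per patient dominate, tests ≈ 4, diagnoses ≈ 2.7,
admissions ≈ 1.5, procedures ≈ 1), uniform event dates over 2012–2017,
sex balanced, ages uniform on 18–90, test values Normal(5.5, 2) with
low/normal/high flags at 4 and 7.  The default 100 patients give on the
order of 2,000 edges, keeping the whole suite in the seconds range;
larger graphs are one config field away.  Everything is a pure function
of the seed.  The generator does **not** model comorbidity structure,
drug–disease correlations or visit episodes, so passing tests certify
the query semantics, not clinical realism.

The fixture graph plants three patients that satisfy the canonical
question exactly (diagnosis 2013 → drugs 2014 → low glucose test 2015,
female, no hypertension) plus one near-miss whose test precedes the
drugs; the planted patients' edges to the four canonical entities are
fully controlled so the expected count is exactly 3.

Question templates follow the head-final word order of the source
questions ("with X patients count"), which lets the Latin-script
fixtures exercise the same grammar as the unsegmented ones; gold answers
are always computed by the brute-force oracle.  Coverage and precision
on the generated set are 1.0 by construction — any miss is a pipeline
bug, not noise.

## Evaluation harness

coverage = answered/total, precision = correct/answered (undefined, not
zero, when nothing is answered).  "Correct" means exact equality for
counts, lists and distributions and relative tolerance 1e-9 for
sum/avg/ratio.  Unanswered questions are categorized as vocabulary,
semantics, unsupported operation, or missing schema property; an
unsupported statistic word surfaces as *vocabulary* (it is, before
anything else, a word the lexicon lacks).

## Known limitations

* Only the three date dialects above are normalized; relative dates
  ("last year") are not.
* Implicit chronology beyond the rank rule, cross-sentence context and
  comparison questions needing two parallel trees are unsupported.
* Linking is purely string-based (no embeddings, no NER); a rare entity
  can link to a near-miss name when the true entity is absent from the
  lexicon.
* The Cypher text is validated structurally (golden files), not against
  a live server.
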