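# cohortqa

Natural-language cohort statistics over patient knowledge graphs.

Clinical researchers constantly need ad-hoc statistics from electronic
medical records — *"How many female patients with hyperglycemia and no
hypertension have low levels of glucose tests after they took
hypoglycemic drugs?"* — but writing the corresponding database queries
requires IT skills most clinicians do not have.  `cohortqa` answers such
*analytic* questions (not fact lookups) directly from natural language,
in both whitespace-delimited and unsegmented (CJK) scripts, over an
EMR-shaped property graph.

## The method

The patient data live in a knowledge graph **G = ⟨Gs, Gd, R⟩**: a schema
graph *Gs = ⟨Ns, Es⟩* of ontology classes (patient, disease, drug, test,
procedure, hospitalization) and typed predicate edges with domain/range;
a data graph *Gd = ⟨Nd, Ed⟩* of instances and time-stamped event triples
(subject, predicate, object); and the typing relation
*R = {(instance, rdf:type, class)}*.  Entities are linked to an external
terminology by `owl:sameAs` edges scored with an averaged string
similarity

```
σ(a, b) = ( L(a, b) + T(a, b) + LCS(a, b) ) / 3
L   = 1 − LevenshteinDistance(a, b) / max(|a|, |b|)
T   = Jaccard( trigrams(a), trigrams(b) )
LCS = LongestCommonSubstring(a, b) / max(|a|, |b|)
```

A question is answered by a five-stage pipeline:

1. **Segmentation** — dates are normalized to `yyyymmdd`, then the text
   is tokenized against a medical lexicon in two modes: *accuracy*
   (greedy longest match) and *full* (every dictionary-consistent
   tokenization), because the best reading ("女患者" vs "女/患者") is
   only decidable later.
2. **Concept linking** — each token is annotated with one of 14 concept
   types (Relation, Instance, Class, Property, Number, EnumValue,
   TimeValue, RangeSeparator, TimeOperator, LogicalOperator,
   StatisticOperator, ArithmeticOperator, Unit, Not); content tokens get
   their top-*k* entity candidates by σ.  Omitted attribute names are
   re-inserted from the schema ("60 years old" → `age`; "female" → `sex`).
3. **Grammar parsing** — the concept-type sequence is parsed under a
   small context-free grammar whose terminals are the 14 types; the
   whole derivation forest is kept.  Elliptical coordination
   (`Relation Instance LogicalOperator Instance`) is repaired by copying
   the governing relation onto bare conjuncts.
4. **Semantic construction and disambiguation** — parse chunks become
   triples joined by Not / And / Or / time operators plus exactly one
   query item (statistic + target), with precedence Not > logical >
   temporal.  Among all (segmentation × parse × entity) candidates, the
   reading with the most schema-realizable triples (then the highest
   summed σ) wins — so "eat Coldrine" resolves to
   ⟨patient, take, Coldrine capsule⟩ rather than ⟨patient, suffer, cold⟩.
5. **Query generation and execution** — the tree is translated to Cypher
   (MATCH patterns for positive triples, WHERE for attribute/negation/
   timestamp constraints, RETURN for the statistic) and executed natively
   over the in-memory graph with six statistic types: list, count, sum,
   avg, distribution, ratio.

## Worked example

Build the bundled fixture (30 patients, 3 of them planted to satisfy the
demonstration question) and ask the question from the shell:

```bash
python -c "
from cohortqa import fixture_graph, fixture_lexicon, save_graph
g = fixture_graph()
save_graph(g, 'demo')
fixture_lexicon(g, 'zh').to_tsv('demo/lexicon_zh.tsv')
fixture_lexicon(g, 'en').to_tsv('demo/lexicon_en.tsv')"

cohortqa ask --graph demo --lexicon demo/lexicon_zh.tsv \
  --question "患有高血糖没有患有高血压的病人吃了降血糖类药后葡萄糖化验结果偏低的女患者数量?" \
  --emit-cypher --verbose --format json
```

prints (diagnostics on stderr, result on stdout):

```
[typed_sequences] [["Relation","Instance","Not","Relation","Instance","Class",
  "Relation","Instance","TimeOperator","Instance","Property","EnumValue",
  "Class","StatisticOperator"], ...]
[serialized] "(<patient, suffer, hyperglycemia> (not <patient, suffer, hypertension>))
  after <patient, take, hypoglycemic drugs>
  after (<patient, have test, blood glucose> <blood glucose, test result, low>)
  <patient, sex, female> <patient, count, ?>"
[census] [8, 9]
[cypher] MATCH (p:`patient`), (p)-[r1:`suffer`]->(n1:`disease` {name: 'hyperglycemia'}), ...
{"excluded": 0, "payload": 3, "type": "count", "undefined": false}
```

The typed sequence is the question's 14 concept types in order; the
serialized line is the canonical tree-like representation (adjacency =
And, `(not …)` = negation, `after` = chronological join, the final
triple the query item) whose drawing has 8 nodes and 9 edges; the answer
is the 3 planted patients.  A distribution query returns grouped counts:

```bash
cohortqa ask --graph demo --lexicon demo/lexicon_en.tsv \
  --question "with hyperglycemia patients sex distribution"
# female  8
# male    4
```

Other entry points: `cohortqa eval --questions FILE [--gold]` computes
coverage (answered/total) and precision (correct/answered) over a
question set; `cohortqa gen --seed N --out DIR` writes a synthetic
graph, its lexicon and a gold-standard question set.

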