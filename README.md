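# tcmkg

Schema-constrained knowledge-graph construction from entity-annotated
classical Chinese-medicine text.

## The problem

Ancient TCM treatises describe clinical reasoning as *syndrome
differentiation and treatment*: from symptoms and signs (tongue
manifestation, pulse condition) through the cause and mechanism of disease
to a therapeutic principle and finally a formula or group of herbs — often
with the formula modified on the spot ("for night sweats, add astragalus
three qian; remove ephedra"). A knowledge graph built from such text must
respect this structure. Connecting every pair of co-occurring entities that
the type system permits floods the graph with relations the text never
asserts: if one passage lists two pulse conditions each with its own
mechanism, only two of the four schema-permitted `cause` edges are real.

`tcmkg` implements a rule-based, **progressive** relation extractor for
entity-annotated articles, aimed at corpus builders and TCM informatics
researchers who have span-level entity annotations (manual, dictionary, or
neural NER output) and want schema-valid triples out.

## The method

A **schema layer** declares 23 entity types (10 of them the "main"
differentiation-and-treatment types, one virtual) and 29 relation types,
each with its allowed (subject type, object type) patterns and permitted
edge attributes (herb `dosage`). Every emitted triple is validated against
it. Extraction proceeds in three stages:

1. **Combination detection.** Maximal contiguous runs of same-group
   entities (mechanisms; therapeutic principles; the mixed
   symptom/tongue/pulse group) become co-occurrence combinations.
   Keyword-triggered formula modifications (`add`/`remove`/`join`/
   `replace … for …`) build *joint-formula* combinations around one basic
   formula or herb group, each modification attached to its nearest
   qualifying basis. Greedy left-to-right slot filling over the four
   process slots — disease/sign → mechanism → principle → remedy — groups
   elements into differentiation-and-treatment (DT) combinations under the
   element-uniqueness principle: a repeated slot closes the current
   combination and starts a new one.
2. **Instantiation.** Combination members are pairwise linked by
   `co_occurrence` (C(n,2) edges); each joint-formula combination
   materializes a *virtual node* carrying basic-formula, addition/removal
   (with `dosage`), joining and basis edges; slot pairs within one DT
   combination are connected member-wise by their declared relation —
   never across combinations. Auxiliary entities (time, physician, book
   title, …) attach by adjacency; the article-ID entity links to every
   node of its article.
3. **Enrichment.** Book and physician reference tables supply author,
   year, dynasty, alias and place edges; the synonym thesaurus built
   during standardization is emitted as
   `<synonym, standard_word_is, standard>` triples.

Entity names are standardized by thesaurus lookup plus element
decomposition–reorganization (tongue entities into six canonical elements,
pulse analogously), keeping raw/cooked herb states distinct. A
**full-connection baseline** (`full_connect`) links every schema-permitted
pair, and the accounting report quantifies the difference:
`reduction % = 100·(B − R_excl)/B`, where `R_excl` excludes virtual-entity
and co-occurrence relations.

## Worked example

```python
from tcmkg import load_default_schema, full_connect, NodeRegistry
from tcmkg.combinations import detect_dt
from tcmkg.instantiate import instantiate_dt
from tcmkg.fixtures import FixtureSpec, generate
from tcmkg.pipeline import extract_corpus

schema = load_default_schema()
fc = generate(FixtureSpec(seed=1, n_articles=100))   # synthetic annotated corpus
res = extract_corpus(fc.articles, schema)
print(len(res.triples), res.registry.n_virtual, res.n_dt_combinations)
print(set(res.triples) == fc.oracle_triples)
```

prints

```
858 17 125
True
```

— from 100 synthetic articles the pipeline produced 858 deduplicated
triples, materialized 17 virtual joint-formula nodes and recognized 125
DT combinations, and the triple set equals the generator's constructive
oracle exactly.

On the parallel-pulse passage (two pulses, each with its own mechanism)
progressive extraction yields exactly the 2 asserted `cause` triples,
while the full-connection baseline yields all 4 schema-permitted ones.

A CLI wraps the same functions: `tcmkg simulate`, `tcmkg annotate`,
`tcmkg extract [--baseline]`, `tcmkg export`, `tcmkg report`.

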