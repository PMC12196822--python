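# Methods

## Scope and assumptions

`tcmkg` consumes *gold* entity spans: typed, offset-anchored, non-overlapping
mentions produced upstream (manual annotation, the bundled dictionary
tagger, or an external NER model whose output is converted to the JSON
Lines span format). The extractor itself is deliberately rule-based and
position/keyword driven — no sentence segmentation, parsing, or
coreference. The underlying assumptions, drawn from how classical medical
prose is organized, are:

* entities taking part in one clinical statement appear **contiguously**,
  separated only by dense punctuation or short conjunctions;
* one differentiation-and-treatment episode mentions each of the four
  process elements (disease/sign, mechanism, principle, remedy) **at most
  once** — a repeat signals a new, parallel episode;
* formula modifications are announced by a small set of **trigger
  keywords** immediately before the herbs or formulas they govern, and the
  clinical basis for a modification sits immediately beside it.

Violations of these assumptions (statements interleaved across episodes,
long-range anaphora, implicit bases) are outside what the rules can
recover; such relations are simply not emitted.

## Schema layer

The default configuration declares 23 entity types and 29 relation types.
The type and relation inventories are fixed by their source; the
**(subject, object) pattern table is a reconstruction**, because only
per-type pattern counts were ever published. Every pattern in
`data/default_schema.yaml` is either backed by an explicit statement
(mechanism —`cause`→ pulse; principle —`use`→ formula; formula/joint
formula —`consist_of`→ herb with `dosage`) or chosen as the minimal
standard-semantics completion; the file is user-editable and the engine
never hard-codes patterns. Two consequences:

* `co_occurrence` is symmetric — its pattern set is closed under pair
  reversal — but each unordered pair is stored once, directed by document
  order, to avoid double counting;
* the synonym relation `standard_word_is` is **not** one of the 29: the
  published relation inventory does not contain it although synonym
  triples are stored. It is handled as a schema-exempt relation valid
  exactly when subject and object share an entity type.

Eight relations (`basic_formula_is`, `composition_of_basic_formula_is`,
herb/formula addition and removal, and the three basis relations)
*structure* the joint-formula combination itself. They are emitted only
during materialization; everywhere else — DT instantiation, auxiliary
attachment — the virtual node behaves as a plain formula entity. Without
this split, a (virtual node, mechanism) slot pair would spuriously emit
basis edges.

## Tunable parameters

All distances are Unicode code points; all defaults live in
`Stage1Config` / `PipelineConfig` and the lexicon YAML.

| parameter | default | meaning |
|---|---|---|
| `max_gap` | 6 | longest text gap inside a combination; classical prose punctuates densely, so 6 covers a delimiter plus a short conjunction |
| `keyword_window` | 8 | how far before a herb/formula group a trigger keyword may sit (longest default keyword plus a delimiter) |
| `basis_window` | 30 | search radius for a modification basis; ties broken toward the preceding side, which in practice states the indication first |
| `aux_window` | 30 | same rule for auxiliary-entity attachment |
| `link_article_id` | on | article-ID entity linked to every node of its article |

Trigger keywords, delimiters, conjunctions, replacement patterns
(two-capture regexes: group 1 incoming, group 2 outgoing herbs) and the
dose expression are an editable lexicon (`data/default_lexicon.yaml`) with
both classical-Chinese and ASCII defaults. Doses are kept as **raw
strings** on the edge (`dosage` attribute): classical dose notations are
too heterogeneous to parse into units without a dedicated normalizer.

A lone formula mention creates **no** virtual node — the virtual entity
exists to carry modification structure, so it is materialized only when at
least one join/add/remove element is present or the basic element is a
herb group of two or more herbs. A herb-group basic yields
`composition_of_basic_formula_is` edges instead of `basic_formula_is`.

## Standardization

Exact (surface, type) thesaurus lookup first; unresolved tongue/pulse
surfaces then go through element decomposition–reorganization: the surface
is tiled leftmost-longest over the element and modifier keyword
vocabulary, matched element keywords are re-emitted grouped by element in
the canonical element order (tongue: spirit, body color, form, motility,
fur color, fur texture), modifiers prepended in original order. Keywords
within one element are ordered by lexicon rank, not by position, which
makes the operation idempotent and invariant to the order the writer
listed the elements in. Any unmatched residue aborts canonicalization —
the surface is kept verbatim and flagged, never half-normalized. The pulse
element inventory (position, rate, rhythm, strength, shape) is a
reconstruction on the same pattern and is marked as such in the config.
Raw/cooked state prefixes on herbs are preserved through normalization;
the processed and unprocessed materials are distinct entities. Ambiguous
abbreviations (the classic "Shao 芍", either red or white peony root) stay
verbatim and land in the unresolved report for human triage — this
package intentionally ships no automatic disambiguation. All non-identity
resolutions are recoverable as `standard_word_is` triples, so
standardization loses no surface forms.

## Baseline and accounting

The full-connection baseline links every ordered pair of deduplicated
co-article entities by every declared relation except `co_occurrence`,
creating no virtual nodes — the comparison column for the progressive
method. The report identities are pure arithmetic over category counts
(see `KGReport`); percentages are rounded half-up to two decimals to match
the published presentation. "Virtual-entity relationships" are defined as
triples with a virtual node at either end; this definition makes all six
identities hold on every run, which the pipeline asserts as a self-audit.
When the reduction percentage is measured on synthetic corpora, the
article-ID linkage is switched off on the progressive side, because the
baseline by construction connects annotated spans only — otherwise the
comparison would mix bookkeeping edges into a statement about extraction
behaviour.

## Synthetic corpus and what it shows

The generator (`tcmkg.fixtures`) emits articles from five structural
templates — parallel sign–cause pairs, full DT processes, partial
processes, joint-formula episodes (additions with doses, removals, joined
formulas, herb-group basics, replacements), and auxiliary contexts — and
derives the expected triples **constructively while writing the text**,
without calling the extractor or the schema helpers. Default mix: 25 %
parallel pairs, 25 % full, 20 % partial, 20 % joint formula, 10 %
auxiliary; 2–3 members per combination, 40 surfaces per type, doses on
~70 % of modified herbs. Same seed ⇒ byte-identical corpus and oracle.

Passing the oracle-equality test shows the implementation realizes its
stated rules exactly on text that obeys the contiguity and keyword
assumptions. It does **not** show robustness to real classical prose:
annotation noise, keyword paraphrase, long-range bases, entities shared
between episodes, or NER errors are all outside the templates. The
corpus-scale published figures (hundreds of thousands of entities, NER
F1) are functions of a specific unavailable corpus and are therefore
checked only as arithmetic identities over their published category
counts, plus the directional property — progressive ≤ baseline on the
comparable core — which holds on every generated corpus.

Test and acceptance runs use 100-article corpora; end to end this is a
few seconds, and detection behaviour is template-local, so larger corpora
only repeat the same structures.

## Known limitations

* Pattern table, auxiliary relation choices, and pulse elements are
  reconstructions (flagged inline in the config files).
* Segmenting joint-formula episodes at unkeyworded formula/herb-group
  boundaries is a heuristic; prose that chains two regimens without
  triggers will merge or split imperfectly.
* A DT combination never crosses an article boundary.
* No dose parsing, no disambiguation of abbreviated herb names, no
  neural NER — ingestion of external NER output is format-level only.
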