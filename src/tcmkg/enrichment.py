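"""Stage 3: enrich the graph from external reference tables.

Book-title nodes matched in the ancient-book information table gain author,
completion-year and dynasty edges; physician nodes matched in the
biographical table gain alias, dynasty and place edges; the synonym triples
produced by standardization are appended.  Enrichment is purely additive
and idempotent: the input triples are a subset of the output, and re-running
adds nothing new.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .corpus_io import BookInfoRecord, PhysicianRecord, _norm_title
from .instantiate import EntityNode, NodeRegistry, Triple
from .schema import SchemaLayer, SYNONYM_RELATION
from .standardization import Thesaurus, emit_synonym_triples

logger = logging.getLogger(__name__)

__all__ = ["enrich"]


def _checked_append(out: list[Triple], seen: set[Triple], schema: SchemaLayer,
                    subj: EntityNode, rel: str, obj: EntityNode) -> None:
    from .schema import validate_triple_types

    if not validate_triple_types(schema, subj.entity_type, rel, obj.entity_type):
        logger.warning("enrichment: dropping schema-invalid <%s, %s, %s>",
                       subj.name, rel, obj.name)
        return
    t = Triple(subject=subj.node_id, relation=rel, object=obj.node_id)
    if t not in seen:
        seen.add(t)
        out.append(t)


def enrich(
    triples: Sequence[Triple],
    registry: NodeRegistry,
    schema: SchemaLayer,
    books: Mapping[str, BookInfoRecord] | None = None,
    physicians: Mapping[str, PhysicianRecord] | None = None,
    thesaurus: Thesaurus | None = None,
) -> list[Triple]:
    """Supplement book, physician and synonym relations.

    Matching is by exact (whitespace-normalized) name against the reference
    tables — run after standardization so aliases do not fragment matches.
    Unmatched nodes are left untouched.  New nodes (authors, years,
    dynasties, places, aliases) are created in ``registry`` as needed.
    """
    books = books or {}
    physicians = physicians or {}
    out = list(triples)
    seen = set(out)

    # snapshot: enrichment adds nodes while iterating
    existing = list(registry.nodes.values())

    for node in existing:
        if node.entity_type == "book_title":
            rec = books.get(_norm_title(node.name))
            if rec is None:
                continue
            if rec.author:
                author = registry.get_or_create("physician", rec.author, count=False)
                _checked_append(out, seen, schema, node, "the_author_is", author)
            if rec.year:
                year = registry.get_or_create("book_year", rec.year, count=False)
                _checked_append(out, seen, schema, node, "be_written_in", year)
            if rec.dynasty:
                dyn = registry.get_or_create("book_dynasty", rec.dynasty, count=False)
                _checked_append(out, seen, schema, node, "in", dyn)
        elif node.entity_type == "physician":
            rec = physicians.get(node.name)
            if rec is None:
                continue
            for alias in rec.aliases:
                anode = registry.get_or_create("physician", alias, count=False)
                _checked_append(out, seen, schema, anode, SYNONYM_RELATION, node)
            if rec.dynasty:
                dyn = registry.get_or_create("book_dynasty", rec.dynasty, count=False)
                _checked_append(out, seen, schema, node, "active_in", dyn)
            for place in rec.places:
                pnode = registry.get_or_create("geographical_name", place, count=False)
                _checked_append(out, seen, schema, node, "in", pnode)

    if thesaurus is not None:
        for e in thesaurus.non_identity_entries():
            registry.get_or_create(e.entity_type, e.synonym, count=False)
            registry.get_or_create(e.entity_type, e.standard, count=False)
        for t in emit_synonym_triples(thesaurus):
            if t not in seen:
                seen.add(t)
                out.append(t)
    return out
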