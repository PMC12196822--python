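"""Full-connection baseline: link every schema-permitted co-article pair.

The comparison extractor against which progressive extraction is measured.
It ignores context entirely: within one article, every ordered pair of
distinct (deduplicated) entities is connected by every relation the schema
layer declares for that type pair.  No virtual entities are created and no
co-occurrence edges are emitted, so its output is directly comparable to the
progressive pipeline's count after excluding virtual-entity and
co-occurrence relations.
"""

from __future__ import annotations

from typing import Sequence

from .corpus_io import AnnotatedArticle
from .instantiate import NodeRegistry, Triple
from .schema import SchemaLayer, allowed_relations

__all__ = ["full_connect", "full_connect_corpus"]


def full_connect(
    article: AnnotatedArticle,
    schema: SchemaLayer,
    registry: NodeRegistry | None = None,
    namer=None,
) -> list[Triple]:
    """All schema-permitted triples over the article's deduplicated entities.

    For every ordered pair of distinct nodes and every relation declared for
    (subject type, object type) — except ``co_occurrence`` — one triple.
    """
    namer = namer or (lambda sp: sp.surface)
    registry = registry if registry is not None else NodeRegistry()
    nodes = []
    seen: set[str] = set()
    for sp in article.spans:
        node = registry.get_or_create(sp.entity_type, namer(sp))
        if node.node_id not in seen:
            seen.add(node.node_id)
            nodes.append(node)
    out: list[Triple] = []
    for a in nodes:
        for b in nodes:
            if a.node_id == b.node_id:
                continue
            for rel in allowed_relations(schema, a.entity_type, b.entity_type):
                if rel == "co_occurrence":
                    continue
                out.append(Triple(subject=a.node_id, relation=rel, object=b.node_id,
                                  provenance=article.article_id))
    return out


def full_connect_corpus(
    corpus: Sequence[AnnotatedArticle],
    schema: SchemaLayer,
    namer=None,
) -> tuple[NodeRegistry, list[Triple]]:
    """Article-scoped full connection over a corpus; triples deduplicated."""
    registry = NodeRegistry()
    seen: set[Triple] = set()
    out: list[Triple] = []
    for article in corpus:
        for t in full_connect(article, schema, registry=registry, namer=namer):
            if t not in seen:
                seen.add(t)
                out.append(t)
    return registry, out
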