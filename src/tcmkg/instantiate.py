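"""Stage 2 of progressive relation extraction: triple instantiation.

Combinations and remaining entities are turned into relation/attribute
triples under schema-layer constraints:

* members of a same-type combination are pairwise connected by
  ``co_occurrence`` (canonical document-order direction, so each unordered
  pair is stored once);
* every joint-formula combination materializes one *virtual* node which
  carries the basic-formula, herb-addition/removal, formula-joining and
  basis edges; downstream the virtual node stands in for a formula;
* within one differentiation-and-treatment combination, every slot pair
  with a declared schema pattern is connected member-wise; no triple is
  ever emitted *between* two DT combinations;
* auxiliary entities (time, age, gender, staging, prognosis, constitution,
  geography, and the disease nature/location elements) attach to their
  nearest schema-compatible entity; physicians and book titles attach to
  every entity of the nearest DT combination; the article-ID entity links
  to every node of its article.

Herb doses are carried as the ``dosage`` edge attribute, never parsed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .combinations import (
    DTCombination,
    DT_SLOTS,
    Element,
    JointFormulaCombination,
    SameTypeCombination,
    Stage1Config,
    element_spans,
)
from .corpus_io import AnnotatedArticle, EntitySpan
from .schema import SchemaLayer, allowed_relations, validate_pattern

logger = logging.getLogger(__name__)

__all__ = [
    "EntityNode",
    "Triple",
    "NodeRegistry",
    "cooccurrence_edges",
    "materialize_joint_formula",
    "instantiate_dt",
    "attach_auxiliary",
    "NEAREST_ATTACH_TYPES",
    "COMBINATION_ATTACH_TYPES",
]

#: auxiliary types linked to the nearest single compatible entity
NEAREST_ATTACH_TYPES = frozenset({
    "time", "age", "gender", "staging", "prognosis", "constitution",
    "geographical_name", "nature_of_disease", "location_of_disease",
})

#: auxiliary types linked to every entity of the nearest DT combination
COMBINATION_ATTACH_TYPES = frozenset({"physician", "book_title"})


@dataclass(frozen=True)
class EntityNode:
    node_id: str
    entity_type: str
    name: str
    is_virtual: bool = False


@dataclass(frozen=True)
class Triple:
    """Subject/relation/object over node ids, with optional edge attributes.

    Equality and hashing ignore provenance, so corpus-level triple sets
    deduplicate repeated statements while keeping one article of origin.
    """

    subject: str
    relation: str
    object: str
    attributes: tuple[tuple[str, str], ...] = ()
    provenance: str = field(default="", compare=False)

    @property
    def attr_dict(self) -> dict[str, str]:
        return dict(self.attributes)


def _attrs(d: Mapping[str, str] | None) -> tuple[tuple[str, str], ...]:
    if not d:
        return ()
    return tuple(sorted(d.items()))


class NodeRegistry:
    """Deduplicates nodes by (entity type, name) and counts mentions.

    Non-virtual node ids are ``<type>:<name>`` — deterministic, so
    independently constructed registries agree.  Virtual joint-formula ids
    are ``JF:<article_id>:<ordinal>``.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, EntityNode] = {}
        self.mention_counts: Counter[str] = Counter()

    def get_or_create(self, entity_type: str, name: str, *, count: bool = True) -> EntityNode:
        node_id = f"{entity_type}:{name}"
        node = self.nodes.get(node_id)
        if node is None:
            node = EntityNode(node_id=node_id, entity_type=entity_type, name=name)
            self.nodes[node_id] = node
        if count:
            self.mention_counts[node_id] += 1
        return node

    def create_virtual(self, article_id: str, ordinal: int) -> EntityNode:
        node_id = f"JF:{article_id}:{ordinal}"
        node = EntityNode(node_id=node_id, entity_type="joint_formula",
                          name=node_id, is_virtual=True)
        self.nodes[node_id] = node
        self.mention_counts[node_id] += 1
        return node

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_virtual(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_virtual)


def _checked(schema: SchemaLayer, subj: EntityNode, relation: str, obj: EntityNode,
             attributes: Mapping[str, str] | None = None, provenance: str = "",
             ) -> Triple | None:
    """Build a schema-validated triple, or drop it with a log record."""
    if not validate_pattern(schema, subj.entity_type, relation, obj.entity_type):
        logger.warning(
            "dropping schema-invalid triple <%s, %s, %s> (%s -> %s)",
            subj.name, relation, obj.name, subj.entity_type, obj.entity_type,
        )
        return None
    if attributes:
        rel = schema.relation_types[relation]
        bad = set(attributes) - set(rel.attributes)
        if bad:
            logger.warning("dropping undeclared attributes %s on %r", bad, relation)
            attributes = {k: v for k, v in attributes.items() if k in rel.attributes}
    return Triple(subject=subj.node_id, relation=relation, object=obj.node_id,
                  attributes=_attrs(attributes), provenance=provenance)


# ---------------------------------------------------------------------------
# co-occurrence edges
# ---------------------------------------------------------------------------

def cooccurrence_edges(
    combo: SameTypeCombination,
    registry: NodeRegistry,
    schema: SchemaLayer,
    article_id: str = "",
    namer=None,
) -> list[Triple]:
    """One ``co_occurrence`` triple per unordered member pair (C(n,2) total),
    directed from the earlier to the later mention."""
    namer = namer or (lambda sp: sp.surface)
    nodes = [registry.get_or_create(m.entity_type, namer(m), count=False)
             for m in combo.members]
    out: list[Triple] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i].node_id == nodes[j].node_id:
                continue  # repeated mention of one entity: no self-loop
            t = _checked(schema, nodes[i], "co_occurrence", nodes[j],
                         provenance=article_id)
            if t is not None:
                out.append(t)
    return out


# ---------------------------------------------------------------------------
# joint-formula materialization
# ---------------------------------------------------------------------------

#: relations that structure the joint-formula combination itself; they are
#: emitted only during materialization — in DT instantiation and auxiliary
#: attachment the virtual node behaves like a plain formula entity
JF_STRUCTURAL_RELATIONS = frozenset({
    "basic_formula_is", "composition_of_basic_formula_is",
    "add_herb_to_basic_formula", "remove_herb_to_basic_formula",
    "add_formula_to_basic_formula", "basis_for_adding_herb",
    "basis_for_removing_herb", "basis_for_adding_formula",
})

_BASIS_RELATION = {
    "add": "basis_for_adding_herb",
    "remove": "basis_for_removing_herb",
    "join": "basis_for_adding_formula",
}
_GROUP_RELATION = {
    "add": "add_herb_to_basic_formula",
    "remove": "remove_herb_to_basic_formula",
    "join": "add_formula_to_basic_formula",
}


def materialize_joint_formula(
    jf: JointFormulaCombination,
    registry: NodeRegistry,
    schema: SchemaLayer,
    article_id: str,
    ordinal: int,
    namer=None,
) -> tuple[EntityNode, list[Triple]]:
    """Create the virtual node and its incident triples.

    A formula basic yields one ``basic_formula_is`` edge; a herb-group basic
    yields one ``composition_of_basic_formula_is`` edge per herb.  Herb
    modifications carry their dose as the ``dosage`` attribute; each basis
    (a single entity or a whole combination, expanded member-wise) hangs off
    the virtual node under the matching basis relation.
    """
    namer = namer or (lambda sp: sp.surface)
    vnode = registry.create_virtual(article_id, ordinal)
    out: list[Triple] = []

    def emit(rel: str, sp: EntitySpan, with_dose: bool = False) -> None:
        obj = registry.get_or_create(sp.entity_type, namer(sp), count=False)
        attrs = None
        if with_dose and sp in jf.dosages:
            attrs = {"dosage": jf.dosages[sp]}
        t = _checked(schema, vnode, rel, obj, attributes=attrs, provenance=article_id)
        if t is not None:
            out.append(t)

    if jf.basic_is_group:
        for sp in jf.basic_formula:
            emit("composition_of_basic_formula_is", sp, with_dose=True)
    else:
        emit("basic_formula_is", jf.basic_formula)

    for group in jf.groups:
        rel = _GROUP_RELATION[group.kind]
        for sp in group.spans:
            emit(rel, sp, with_dose=group.kind in ("add", "remove"))
        if group.basis is not None:
            brel = _BASIS_RELATION[group.kind]
            for sp in element_spans(group.basis):
                emit(brel, sp)
    return vnode, out


# ---------------------------------------------------------------------------
# differentiation-and-treatment instantiation
# ---------------------------------------------------------------------------

def _slot_nodes(
    el: Element,
    registry: NodeRegistry,
    jf_nodes: Mapping[int, EntityNode],
    namer,
) -> list[EntityNode]:
    if isinstance(el, JointFormulaCombination):
        return [jf_nodes[id(el)]]
    return [registry.get_or_create(sp.entity_type, namer(sp), count=False)
            for sp in element_spans(el)]


def instantiate_dt(
    dt: DTCombination,
    registry: NodeRegistry,
    schema: SchemaLayer,
    article_id: str = "",
    jf_nodes: Mapping[int, EntityNode] | None = None,
    namer=None,
) -> list[Triple]:
    """Connect slot pairs of one DT combination member-wise.

    Every ordered pair of distinct filled slots is considered; each
    (subject, object) member pair gets one triple per declared relation
    (``co_occurrence`` excluded — that edge belongs to stage-1 combinations).
    A joint-formula element is represented solely by its virtual node.
    Combinations share their relation across members.  Nothing connects two
    different DT combinations.
    """
    namer = namer or (lambda sp: sp.surface)
    jf_nodes = jf_nodes or {}
    out: list[Triple] = []
    filled = [(s, dt.slots[s]) for s in DT_SLOTS if s in dt.slots]
    for si, el_i in filled:
        nodes_i = _slot_nodes(el_i, registry, jf_nodes, namer)
        for sj, el_j in filled:
            if si == sj:
                continue
            nodes_j = _slot_nodes(el_j, registry, jf_nodes, namer)
            for a in nodes_i:
                for b in nodes_j:
                    for rel in allowed_relations(schema, a.entity_type, b.entity_type):
                        if rel == "co_occurrence" or rel in JF_STRUCTURAL_RELATIONS:
                            continue
                        t = _checked(schema, a, rel, b, provenance=article_id)
                        if t is not None:
                            out.append(t)
    return out


# ---------------------------------------------------------------------------
# auxiliary attachment
# ---------------------------------------------------------------------------

def _link_either_direction(schema: SchemaLayer, a: EntityNode, b: EntityNode,
                           article_id: str) -> Triple | None:
    def usable(x: EntityNode, y: EntityNode) -> list[str]:
        return [r for r in allowed_relations(schema, x.entity_type, y.entity_type)
                if r != "co_occurrence" and r not in JF_STRUCTURAL_RELATIONS]

    rels = usable(a, b)
    if rels:
        return _checked(schema, a, rels[0], b, provenance=article_id)
    rels = usable(b, a)
    if rels:
        return _checked(schema, b, rels[0], a, provenance=article_id)
    return None


def attach_auxiliary(
    spans: Sequence[EntitySpan],
    dts: Sequence[DTCombination],
    registry: NodeRegistry,
    schema: SchemaLayer,
    article_id: str = "",
    window: int = 30,
    jf_nodes: Mapping[int, EntityNode] | None = None,
    namer=None,
) -> list[Triple]:
    """Link non-process entities into the graph.

    Nearest-attach types pick the closest span (by character distance, ties
    to the preceding side, within ``window``) with which the schema declares
    a relation in either direction.  Physician / book-title entities link to
    every entity of the character-nearest DT combination.
    """
    namer = namer or (lambda sp: sp.surface)
    jf_nodes = jf_nodes or {}
    out: list[Triple] = []

    dt_extents = []
    for dt in dts:
        ms = dt.member_spans()
        dt_extents.append((ms[0].start, ms[-1].end, dt))

    for sp in spans:
        node = registry.get_or_create(sp.entity_type, namer(sp), count=False)
        if sp.entity_type in NEAREST_ATTACH_TYPES:
            best = None
            best_key = None
            for other in spans:
                if other is sp:
                    continue
                if other.end <= sp.start:
                    dist, side = sp.start - other.end, 0
                elif other.start >= sp.end:
                    dist, side = other.start - sp.end, 1
                else:
                    continue
                if dist > window:
                    continue
                onode = registry.get_or_create(other.entity_type, namer(other), count=False)
                t = _link_either_direction(schema, node, onode, article_id)
                if t is None:
                    continue
                key = (dist, side)
                if best_key is None or key < best_key:
                    best, best_key = t, key
            if best is not None:
                out.append(best)
        elif sp.entity_type in COMBINATION_ATTACH_TYPES:
            if not dt_extents:
                continue
            def dt_dist(ext: tuple[int, int, DTCombination]) -> tuple[int, int]:
                start, end, _ = ext
                if end <= sp.start:
                    return (sp.start - end, 0)
                if start >= sp.end:
                    return (start - sp.end, 1)
                return (0, 0)
            _, _, nearest = min(dt_extents, key=dt_dist)
            targets: list[EntityNode] = []
            for el in nearest.slots.values():
                targets.extend(_slot_nodes(el, registry, jf_nodes, namer))
            seen: set[str] = set()
            for tgt in targets:
                if tgt.node_id in seen:
                    continue
                seen.add(tgt.node_id)
                t = _link_either_direction(schema, node, tgt, article_id)
                if t is not None:
                    out.append(t)
    return out
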