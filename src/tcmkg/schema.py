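"""Schema layer: entity types, relation types, and allowed type patterns.

The schema layer is the type-level design of the knowledge graph.  It declares
which entity types exist (23 in the default configuration, of which 10 are the
"main" differentiation-and-treatment types and one — the joint formula — is
virtual), which relation types exist (29 by default), which (subject type,
object type) pairs each relation may connect, and which attributes (e.g. herb
``dosage``) an edge of a given relation may carry.

Every triple the extraction pipeline emits is validated against these
patterns; the schema therefore acts as the hard constraint that separates
"declared possible" from "actually expressed" relations.

The synonym relation ``standard_word_is`` produced by the standardization
stage is deliberately *not* part of the 29 declared relations: it links two
surface forms of the same entity type and is validated by that rule alone
(see :func:`validate_triple_types`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "EntityTypeDef",
    "RelationTypeDef",
    "SchemaLayer",
    "SchemaError",
    "SchemaLookupError",
    "SchemaValidationError",
    "SYNONYM_RELATION",
    "load_schema",
    "load_default_schema",
    "validate_pattern",
    "allowed_relations",
]

#: Relation used for <synonym, the standard word is, standard> triples.
#: Schema-exempt: valid iff subject and object share an entity type.
SYNONYM_RELATION = "standard_word_is"


class SchemaError(Exception):
    """Base class for schema configuration problems."""


class SchemaValidationError(SchemaError):
    """A schema file parsed but violates a structural invariant."""


class SchemaLookupError(SchemaError, KeyError):
    """A name used in a query is not declared in the schema.

    ``argument`` identifies which query argument failed ("subject_type",
    "relation", or "object_type").
    """

    def __init__(self, argument: str, name: str) -> None:
        self.argument = argument
        self.name = name
        super().__init__(f"undeclared {argument}: {name!r}")


@dataclass(frozen=True)
class EntityTypeDef:
    name: str
    label: str = ""
    is_main: bool = False
    is_virtual: bool = False


@dataclass(frozen=True)
class RelationTypeDef:
    name: str
    patterns: frozenset[tuple[str, str]]
    attributes: frozenset[str] = frozenset()
    label: str = ""


@dataclass
class SchemaLayer:
    """Validated collection of entity-type and relation-type declarations."""

    entity_types: dict[str, EntityTypeDef] = field(default_factory=dict)
    relation_types: dict[str, RelationTypeDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SchemaLayer":
        try:
            raw_ents = cfg["entity_types"]
            raw_rels = cfg["relation_types"]
        except (KeyError, TypeError) as exc:
            raise SchemaValidationError(
                f"schema config must define top-level keys "
                f"'entity_types' and 'relation_types' (missing: {exc})"
            ) from exc
        ents: dict[str, EntityTypeDef] = {}
        for name, spec in raw_ents.items():
            spec = spec or {}
            if not isinstance(spec, Mapping):
                raise SchemaValidationError(
                    f"entity_types.{name}: expected a mapping, got {type(spec).__name__}"
                )
            ents[name] = EntityTypeDef(
                name=name,
                label=str(spec.get("label", name)),
                is_main=bool(spec.get("is_main", False)),
                is_virtual=bool(spec.get("is_virtual", False)),
            )
        rels: dict[str, RelationTypeDef] = {}
        for name, spec in raw_rels.items():
            spec = spec or {}
            pats = spec.get("patterns", [])
            norm: set[tuple[str, str]] = set()
            for p in pats:
                if not (isinstance(p, (list, tuple)) and len(p) == 2):
                    raise SchemaValidationError(
                        f"relation_types.{name}.patterns: each pattern must be a "
                        f"[subject, object] pair, got {p!r}"
                    )
                norm.add((str(p[0]), str(p[1])))
            rels[name] = RelationTypeDef(
                name=name,
                patterns=frozenset(norm),
                attributes=frozenset(str(a) for a in spec.get("attributes", [])),
                label=str(spec.get("label", name)),
            )
        return cls(entity_types=ents, relation_types=rels)

    def to_dict(self) -> dict:
        out: dict = {"entity_types": {}, "relation_types": {}}
        for name in sorted(self.entity_types):
            e = self.entity_types[name]
            d: dict = {"label": e.label}
            if e.is_main:
                d["is_main"] = True
            if e.is_virtual:
                d["is_virtual"] = True
            out["entity_types"][name] = d
        for name in sorted(self.relation_types):
            r = self.relation_types[name]
            d = {"patterns": [list(p) for p in sorted(r.patterns)]}
            if r.attributes:
                d["attributes"] = sorted(r.attributes)
            out["relation_types"][name] = d
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), allow_unicode=True, sort_keys=False),
            encoding="utf-8",
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for rel in self.relation_types.values():
            for subj, obj in rel.patterns:
                for t in (subj, obj):
                    if t not in self.entity_types:
                        raise SchemaValidationError(
                            f"relation {rel.name!r}: pattern ({subj!r}, {obj!r}) "
                            f"references undeclared entity type {t!r}"
                        )

    # -- queries -----------------------------------------------------------

    @property
    def main_types(self) -> list[str]:
        return [n for n, e in self.entity_types.items() if e.is_main]

    @property
    def virtual_types(self) -> list[str]:
        return [n for n, e in self.entity_types.items() if e.is_virtual]

    def require_entity_type(self, name: str, argument: str = "entity_type") -> EntityTypeDef:
        try:
            return self.entity_types[name]
        except KeyError:
            raise SchemaLookupError(argument, name) from None

    def require_relation(self, name: str) -> RelationTypeDef:
        try:
            return self.relation_types[name]
        except KeyError:
            raise SchemaLookupError("relation", name) from None

    def copy(self) -> "SchemaLayer":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SchemaLayer):
            return NotImplemented
        return (
            self.entity_types == other.entity_types
            and self.relation_types == other.relation_types
        )


def load_schema(path: str | Path) -> SchemaLayer:
    """Load and validate a schema-layer YAML file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaValidationError(f"cannot parse schema file {path}: {exc}") from exc
    return SchemaLayer.from_dict(cfg)


def load_default_schema() -> SchemaLayer:
    """Load the bundled default schema (23 entity types, 29 relations)."""
    text = resources.files("tcmkg.data").joinpath("default_schema.yaml").read_text("utf-8")
    return SchemaLayer.from_dict(yaml.safe_load(text))


def validate_pattern(
    schema: SchemaLayer, subject_type: str, relation: str, object_type: str
) -> bool:
    """True iff (subject_type, object_type) is a declared pattern of relation.

    Direction-sensitive.  Raises :class:`SchemaLookupError` identifying the
    offending argument when any of the three names is undeclared.
    """
    schema.require_entity_type(subject_type, "subject_type")
    schema.require_entity_type(object_type, "object_type")
    rel = schema.require_relation(relation)
    return (subject_type, object_type) in rel.patterns


def allowed_relations(
    schema: SchemaLayer, subject_type: str, object_type: str
) -> list[str]:
    """All relation names declared for (subject_type, object_type), sorted."""
    schema.require_entity_type(subject_type, "subject_type")
    schema.require_entity_type(object_type, "object_type")
    return sorted(
        name
        for name, rel in schema.relation_types.items()
        if (subject_type, object_type) in rel.patterns
    )


def validate_triple_types(
    schema: SchemaLayer, subject_type: str, relation: str, object_type: str
) -> bool:
    """Pattern check that also admits the schema-exempt synonym relation."""
    if relation == SYNONYM_RELATION:
        schema.require_entity_type(subject_type, "subject_type")
        schema.require_entity_type(object_type, "object_type")
        return subject_type == object_type
    return validate_pattern(schema, subject_type, relation, object_type)
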