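"""End-to-end progressive extraction over an annotated corpus.

Per article: stage-1 combination detection, stage-2 triple instantiation
(co-occurrence edges, virtual joint-formula materialization, DT slot-pair
instantiation, auxiliary attachment, article-ID linkage), with optional
name standardization applied at node creation.  Stage-3 enrichment and the
accounting report are separate calls (:mod:`tcmkg.enrichment`,
:mod:`tcmkg.report`) so each stage stays independently testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .baseline import full_connect_corpus
from .combinations import (
    Stage1Config,
    attach_bases,
    detect_dt,
    detect_joint_formula,
    detect_same_type,
)
from .corpus_io import AnnotatedArticle, EntitySpan
from .instantiate import (
    NodeRegistry,
    Triple,
    attach_auxiliary,
    cooccurrence_edges,
    instantiate_dt,
    materialize_joint_formula,
)
from .report import KGReport, report_from_triples
from .schema import SchemaLayer, load_default_schema

__all__ = ["PipelineConfig", "ExtractionResult", "extract_article", "extract_corpus"]

Namer = Callable[[EntitySpan], str]


@dataclass
class PipelineConfig:
    stage1: Stage1Config = field(default_factory=Stage1Config)
    aux_window: int = 30
    #: link the article-ID entity to every node of its article
    link_article_id: bool = True


@dataclass
class ExtractionResult:
    registry: NodeRegistry
    triples: list[Triple]
    n_same_type_combinations: int = 0
    n_joint_formula_combinations: int = 0
    n_dt_combinations: int = 0

    @property
    def n_cooccurrence(self) -> int:
        return sum(1 for t in self.triples if t.relation == "co_occurrence")

    def report_against(self, baseline_triples: Sequence[Triple]) -> KGReport:
        return report_from_triples(self.triples, baseline_triples, self.registry)


def extract_article(
    article: AnnotatedArticle,
    schema: SchemaLayer,
    cfg: PipelineConfig | None = None,
    registry: NodeRegistry | None = None,
    namer: Namer | None = None,
) -> ExtractionResult:
    """Run stages 1 and 2 on one article."""
    cfg = cfg or PipelineConfig()
    registry = registry if registry is not None else NodeRegistry()
    namer = namer or (lambda sp: sp.surface)
    spans = article.spans
    text = article.text
    aid = article.article_id

    # register every mention once so dedup counts are exact
    for sp in spans:
        registry.get_or_create(sp.entity_type, namer(sp))

    combos = detect_same_type(spans, text, cfg.stage1)
    jfs = detect_joint_formula(spans, text, cfg.stage1)
    for jf in jfs:
        attach_bases(jf, spans, combos, cfg.stage1)
    dts = detect_dt(spans, combos, jfs)

    triples: list[Triple] = []
    for combo in combos:
        triples.extend(cooccurrence_edges(combo, registry, schema, aid, namer=namer))

    jf_nodes = {}
    for i, jf in enumerate(jfs, start=1):
        vnode, ts = materialize_joint_formula(jf, registry, schema, aid, i, namer=namer)
        jf_nodes[id(jf)] = vnode
        triples.extend(ts)

    for dt in dts:
        triples.extend(instantiate_dt(dt, registry, schema, aid, jf_nodes, namer=namer))

    triples.extend(
        attach_auxiliary(spans, dts, registry, schema, aid,
                         window=cfg.aux_window, jf_nodes=jf_nodes, namer=namer)
    )

    if cfg.link_article_id:
        anode = registry.get_or_create("article_id", aid, count=False)
        targets: dict[str, str] = {}
        for sp in spans:
            n = registry.get_or_create(sp.entity_type, namer(sp), count=False)
            targets[n.node_id] = n.entity_type
        for vnode in jf_nodes.values():
            targets[vnode.node_id] = vnode.entity_type
        for node_id in targets:
            triples.append(Triple(subject=anode.node_id, relation="article_id_is",
                                  object=node_id, provenance=aid))

    # article-level dedup, order-preserving
    seen: set[Triple] = set()
    unique = []
    for t in triples:
        if t not in seen:
            seen.add(t)
            unique.append(t)
    return ExtractionResult(
        registry=registry,
        triples=unique,
        n_same_type_combinations=len(combos),
        n_joint_formula_combinations=len(jfs),
        n_dt_combinations=len(dts),
    )


def extract_corpus(
    corpus: Sequence[AnnotatedArticle],
    schema: SchemaLayer | None = None,
    cfg: PipelineConfig | None = None,
    namer: Namer | None = None,
) -> ExtractionResult:
    """Run the progressive pipeline over a corpus with a shared registry.

    Corpus-level triples are deduplicated (equality ignores provenance, so a
    statement repeated across articles is stored once, first article wins).
    """
    schema = schema or load_default_schema()
    cfg = cfg or PipelineConfig()
    registry = NodeRegistry()
    seen: set[Triple] = set()
    triples: list[Triple] = []
    n_combo = n_jf = n_dt = 0
    for article in corpus:
        res = extract_article(article, schema, cfg, registry=registry, namer=namer)
        n_combo += res.n_same_type_combinations
        n_jf += res.n_joint_formula_combinations
        n_dt += res.n_dt_combinations
        for t in res.triples:
            if t not in seen:
                seen.add(t)
                triples.append(t)
    return ExtractionResult(
        registry=registry,
        triples=triples,
        n_same_type_combinations=n_combo,
        n_joint_formula_combinations=n_jf,
        n_dt_combinations=n_dt,
    )
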