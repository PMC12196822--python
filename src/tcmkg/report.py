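"""Graph accounting, deduplication and export.

The accounting report compares progressive extraction against the
full-connection baseline.  With ``R`` the total progressive relationship
count, ``V`` the relationships incident to virtual joint-formula nodes,
``C`` the co-occurrence relationships and ``B`` the baseline count, the
report carries:

* relationships excluding virtual/co-occurrence:  ``R_excl = R − V − C``
* entities excluding virtual nodes:               ``E_excl = E − E_virtual``
* absolute reduction of invalid relationships:    ``B − R_excl``
* relative reduction:                             ``100·(B − R_excl)/B``
* added combination relationships:                ``V + C``
* relative addition:                              ``100·(V + C)/R_excl``

Percentages are rounded half-up to two decimals for display.  Exports cover
a property-graph bulk-import CSV dialect (typed ``:ID``/``:LABEL``/
``:START_ID``/``:TYPE``/``:END_ID`` headers), GraphML, and JSON Lines; the
CSV round-trips losslessly.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .instantiate import EntityNode, NodeRegistry, Triple

__all__ = [
    "KGReport",
    "compute_report",
    "report_from_triples",
    "dedup_nodes",
    "export_graph",
    "import_csv",
]


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals."""
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KGReport:
    n_entities: int
    n_relationships: int
    n_virtual_entities: int
    n_virtual_relationships: int
    n_cooccurrence: int
    n_entities_excl_virtual: int
    n_relationships_excl: int
    baseline_relationships: int
    reduction_abs: int
    reduction_pct: float
    added_abs: int
    added_pct: float

    def to_dict(self) -> dict:
        return asdict(self)

    def check_identities(self) -> None:
        assert self.n_relationships_excl == (
            self.n_relationships - self.n_virtual_relationships - self.n_cooccurrence
        )
        assert self.n_entities_excl_virtual == self.n_entities - self.n_virtual_entities
        assert self.reduction_abs == self.baseline_relationships - self.n_relationships_excl
        assert self.added_abs == self.n_virtual_relationships + self.n_cooccurrence


def compute_report(
    *,
    n_entities: int,
    n_relationships: int,
    n_virtual_entities: int,
    n_virtual_relationships: int,
    n_cooccurrence: int,
    baseline_relationships: int,
) -> KGReport:
    """Evaluate the accounting identities from raw category counts."""
    if baseline_relationships == 0:
        raise ZeroDivisionError(
            "baseline_relationships is 0: reduction percentage is undefined"
        )
    n_relationships_excl = n_relationships - n_virtual_relationships - n_cooccurrence
    if n_relationships_excl == 0:
        raise ZeroDivisionError(
            "no relationships remain after excluding virtual/co-occurrence: "
            "addition percentage is undefined"
        )
    reduction_abs = baseline_relationships - n_relationships_excl
    added_abs = n_virtual_relationships + n_cooccurrence
    return KGReport(
        n_entities=n_entities,
        n_relationships=n_relationships,
        n_virtual_entities=n_virtual_entities,
        n_virtual_relationships=n_virtual_relationships,
        n_cooccurrence=n_cooccurrence,
        n_entities_excl_virtual=n_entities - n_virtual_entities,
        n_relationships_excl=n_relationships_excl,
        baseline_relationships=baseline_relationships,
        reduction_abs=reduction_abs,
        reduction_pct=_pct(reduction_abs, baseline_relationships),
        added_abs=added_abs,
        added_pct=_pct(added_abs, n_relationships_excl),
    )


def _is_virtual_id(node_id: str) -> bool:
    return node_id.startswith("JF:")


def report_from_triples(
    triples: Sequence[Triple],
    baseline_triples: Sequence[Triple],
    registry: NodeRegistry,
) -> KGReport:
    """Derive the category counts from two extracted triple sets."""
    tset = set(triples)
    n_virtual_rel = sum(
        1 for t in tset if _is_virtual_id(t.subject) or _is_virtual_id(t.object)
    )
    n_cooc = sum(1 for t in tset if t.relation == "co_occurrence")
    return compute_report(
        n_entities=len(registry),
        n_relationships=len(tset),
        n_virtual_entities=registry.n_virtual,
        n_virtual_relationships=n_virtual_rel,
        n_cooccurrence=n_cooc,
        baseline_relationships=len(set(baseline_triples)),
    )


def dedup_nodes(mentions: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Deduplicate mentions by (entity type, standardized name).

    Returns ``{node_id: mention_count}`` with ``node_id = "<type>:<name>"``.
    """
    counts: Counter[str] = Counter()
    for etype, name in mentions:
        counts[f"{etype}:{name}"] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _edge_attr_keys(triples: Sequence[Triple]) -> list[str]:
    keys: set[str] = set()
    for t in triples:
        keys.update(t.attr_dict)
    return sorted(keys)


def export_graph(
    registry: NodeRegistry,
    triples: Sequence[Triple],
    outdir: str | Path,
    format: str = "csv",
) -> list[Path]:
    """Write the deduplicated graph in one of csv / graphml / jsonl.

    CSV uses the bulk-import dialect: ``nodes.csv`` with ``:ID``, ``:LABEL``
    and property columns, ``edges.csv`` with ``:START_ID``, ``:TYPE``,
    ``:END_ID`` and edge-property columns (e.g. ``dosage``).  UTF-8, quoted
    fields.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = sorted(registry.nodes.values(), key=lambda n: n.node_id)
    attr_keys = _edge_attr_keys(triples)

    if format == "csv":
        npath, epath = outdir / "nodes.csv", outdir / "edges.csv"
        with open(npath, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, quoting=csv.QUOTE_ALL)
            w.writerow([":ID", ":LABEL", "name", "mention_count"])
            for n in nodes:
                w.writerow([n.node_id, n.entity_type, n.name,
                            registry.mention_counts.get(n.node_id, 0)])
        with open(epath, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, quoting=csv.QUOTE_ALL)
            w.writerow([":START_ID", ":TYPE", ":END_ID", *attr_keys, "article_id"])
            for t in triples:
                ad = t.attr_dict
                w.writerow([t.subject, t.relation, t.object,
                            *[ad.get(k, "") for k in attr_keys], t.provenance])
        return [npath, epath]

    if format == "graphml":
        g = nx.MultiDiGraph()
        for n in nodes:
            g.add_node(n.node_id, entity_type=n.entity_type, name=n.name,
                       mention_count=registry.mention_counts.get(n.node_id, 0))
        for t in triples:
            g.add_edge(t.subject, t.object, relation=t.relation,
                       article_id=t.provenance, **t.attr_dict)
        path = outdir / "graph.graphml"
        nx.write_graphml(g, path)
        return [path]

    if format == "jsonl":
        npath, epath = outdir / "nodes.jsonl", outdir / "edges.jsonl"
        with open(npath, "w", encoding="utf-8") as fh:
            for n in nodes:
                fh.write(json.dumps({
                    "node_id": n.node_id, "entity_type": n.entity_type,
                    "name": n.name, "is_virtual": n.is_virtual,
                    "mention_count": registry.mention_counts.get(n.node_id, 0),
                }, ensure_ascii=False) + "\n")
        with open(epath, "w", encoding="utf-8") as fh:
            for t in triples:
                fh.write(json.dumps({
                    "subject": t.subject, "relation": t.relation,
                    "object": t.object, "attributes": t.attr_dict,
                    "article_id": t.provenance,
                }, ensure_ascii=False) + "\n")
        return [npath, epath]

    raise ValueError(f"unknown export format {format!r}; use csv, graphml or jsonl")


def import_csv(nodes_path: str | Path, edges_path: str | Path
               ) -> tuple[NodeRegistry, list[Triple]]:
    """Parse the CSV export back; inverse of :func:`export_graph` (csv)."""
    registry = NodeRegistry()
    with open(nodes_path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header, data = rows[0], rows[1:]
    for node_id, etype, name, count in data:
        node = EntityNode(node_id=node_id, entity_type=etype, name=name,
                          is_virtual=_is_virtual_id(node_id))
        registry.nodes[node_id] = node
        registry.mention_counts[node_id] = int(count)
    triples: list[Triple] = []
    with open(edges_path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header, data = rows[0], rows[1:]
    attr_keys = header[3:-1]
    for row in data:
        subj, rel, obj = row[0], row[1], row[2]
        attrs = {k: v for k, v in zip(attr_keys, row[3:-1]) if v}
        triples.append(Triple(subject=subj, relation=rel, object=obj,
                              attributes=tuple(sorted(attrs.items())),
                              provenance=row[-1]))
    return registry, triples
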