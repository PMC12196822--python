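"""Entity-name standardization: thesaurus lookup and element decomposition.

Classical texts name the same entity in many ways — abbreviations, aliases,
elements listed in arbitrary order, and state modifiers.  Standardization
maps each surface form to one canonical name while keeping the original
recoverable: every non-identity (synonym, standard) pair is later emitted as
a ``<synonym, standard_word_is, standard>`` triple, so no surface form is
lost from the graph.

Three mechanisms, applied per entity type:

* exact (surface, type) lookup in a synonym thesaurus; unresolved surfaces
  are kept verbatim and flagged for human triage;
* element decomposition–reorganization for tongue and pulse entities: the
  element keywords found in the surface are re-emitted in a canonical
  element order, with position/degree modifiers prepended, which makes the
  result invariant to the order the elements were written in;
* raw/cooked state handling for herbs: a state-prefixed herb is normalized
  on its stem but never merged with the unprefixed herb, because processing
  changes the nature of the material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus_io import EntitySpan
from .instantiate import Triple
from .schema import SYNONYM_RELATION

__all__ = [
    "SynonymEntry",
    "Thesaurus",
    "ThesaurusConflictError",
    "ElementLexicon",
    "load_thesaurus",
    "load_element_lexicons",
    "load_default_element_lexicons",
    "standardize",
    "decompose_recompose",
    "herb_state_normalize",
    "emit_synonym_triples",
    "update_thesaurus",
    "Standardizer",
]

#: state modifiers that keep a processed herb distinct from the raw material
HERB_STATE_PREFIXES = ("生", "熟", "炙", "raw ", "cooked ", "raw-", "cooked-")


class ThesaurusConflictError(Exception):
    """Two different standards claimed for the same (synonym, type)."""


@dataclass(frozen=True)
class SynonymEntry:
    synonym: str
    standard: str
    entity_type: str


@dataclass
class Thesaurus:
    """Map (synonym surface, entity type) -> standard name.

    Standard names implicitly map to themselves; lookups never change the
    entity type.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, entry: SynonymEntry) -> None:
        key = (entry.synonym, entry.entity_type)
        existing = self.entries.get(key)
        if existing is not None and existing != entry.standard:
            raise ThesaurusConflictError(
                f"synonym {entry.synonym!r} ({entry.entity_type}) already maps to "
                f"{existing!r}, refusing silent override with {entry.standard!r}"
            )
        self.entries[key] = entry.standard

    def lookup(self, surface: str, entity_type: str) -> str | None:
        std = self.entries.get((surface, entity_type))
        if std is not None:
            return std
        # a standard name is its own fixed point
        if any(v == surface and k[1] == entity_type for k, v in self.entries.items()):
            return surface
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def non_identity_entries(self) -> list[SynonymEntry]:
        return [
            SynonymEntry(synonym=syn, standard=std, entity_type=etype)
            for (syn, etype), std in sorted(self.entries.items())
            if syn != std
        ]


def load_thesaurus(path: str | Path) -> Thesaurus:
    """Load TSV ``synonym<TAB>standard<TAB>type``."""
    th = Thesaurus()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'synonym<TAB>standard<TAB>type'")
        th.add(SynonymEntry(synonym=parts[0], standard=parts[1], entity_type=parts[2]))
    return th


def save_thesaurus(th: Thesaurus, path: str | Path) -> None:
    lines = [
        f"{syn}\t{std}\t{etype}"
        for (syn, etype), std in sorted(th.entries.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def standardize(surface: str, entity_type: str, thesaurus: Thesaurus) -> tuple[str, bool]:
    """Exact (surface, type) lookup.

    Returns (standard name, resolved flag).  Unresolved surfaces — e.g.
    ambiguous herb abbreviations no thesaurus entry covers — are returned
    verbatim with ``resolved=False``.  Idempotent: a standard name maps to
    itself.
    """
    std = thesaurus.lookup(surface, entity_type)
    if std is None:
        return surface, False
    return std, True


# ---------------------------------------------------------------------------
# element decomposition / reorganization
# ---------------------------------------------------------------------------

@dataclass
class ElementLexicon:
    """Ordered element keyword lists plus position/degree modifiers."""

    elements: list[tuple[str, list[str]]]
    modifiers: list[str] = field(default_factory=list)
    #: characters ignored as separators inside a decomposable surface
    separators: str = " ，、,-"


def load_element_lexicons(path: str | Path) -> dict[str, ElementLexicon]:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _lexicons_from_cfg(cfg)


def load_default_element_lexicons() -> dict[str, ElementLexicon]:
    text = resources.files("tcmkg.data").joinpath("default_elements.yaml").read_text("utf-8")
    return _lexicons_from_cfg(yaml.safe_load(text))


def _lexicons_from_cfg(cfg: dict) -> dict[str, ElementLexicon]:
    out: dict[str, ElementLexicon] = {}
    for name, spec in cfg.items():
        out[name] = ElementLexicon(
            elements=[(el, list(kws)) for el, kws in spec["elements"].items()],
            modifiers=list(spec.get("modifiers", [])),
        )
    return out


def decompose_recompose(surface: str, lex: ElementLexicon) -> tuple[str, bool]:
    """Canonicalize a sign entity by element decomposition–reorganization.

    The surface is tiled leftmost-longest over the union of element and
    modifier keywords.  Matched element keywords are re-emitted grouped by
    element, elements in lexicon (canonical) order and keywords within an
    element in lexicon order; modifiers are prepended in their original
    order.  Any unmatched non-separator residue means the surface is not
    fully decomposable: it is returned verbatim with ``resolved=False``.
    """
    keyword_owner: dict[str, tuple[str, int]] = {}  # kw -> (element, rank)
    for el, kws in lex.elements:
        for rank, kw in enumerate(kws):
            keyword_owner.setdefault(kw, (el, rank))
    vocab = set(keyword_owner) | set(lex.modifiers)
    if not vocab:
        return surface, False
    max_len = max(len(k) for k in vocab)

    found: list[str] = []
    i, n = 0, len(surface)
    residue = False
    while i < n:
        if surface[i] in lex.separators:
            i += 1
            continue
        hit = None
        for L in range(min(max_len, n - i), 0, -1):
            cand = surface[i : i + L]
            if cand in vocab:
                hit = cand
                break
        if hit is None:
            residue = True
            i += 1
        else:
            found.append(hit)
            i += len(hit)
    if residue or not found:
        return surface, False

    modifiers = [k for k in found if k not in keyword_owner]
    per_element: dict[str, list[str]] = {}
    for k in found:
        if k in keyword_owner:
            per_element.setdefault(keyword_owner[k][0], []).append(k)
    parts: list[str] = list(modifiers)
    for el, _ in lex.elements:
        kws = per_element.get(el)
        if kws:
            parts.extend(sorted(set(kws), key=lambda k: keyword_owner[k][1]))
    return "".join(parts), True


def herb_state_normalize(
    surface: str, thesaurus: Thesaurus,
    state_prefixes: Sequence[str] = HERB_STATE_PREFIXES,
) -> tuple[str, bool]:
    """Normalize a herb name, keeping raw/cooked state distinctions.

    A state-prefixed herb has its stem standardized but the prefix retained:
    the processed and unprocessed materials are different entities and are
    never merged.
    """
    for prefix in state_prefixes:
        if surface.startswith(prefix) and len(surface) > len(prefix):
            stem = surface[len(prefix):]
            std, resolved = standardize(stem, "herb", thesaurus)
            return prefix + std, resolved
    return standardize(surface, "herb", thesaurus)


# ---------------------------------------------------------------------------
# synonym triples and thesaurus maintenance
# ---------------------------------------------------------------------------

def emit_synonym_triples(thesaurus: Thesaurus) -> list[Triple]:
    """One ``standard_word_is`` triple per non-identity thesaurus entry."""
    out = []
    for e in thesaurus.non_identity_entries():
        out.append(Triple(
            subject=f"{e.entity_type}:{e.synonym}",
            relation=SYNONYM_RELATION,
            object=f"{e.entity_type}:{e.standard}",
        ))
    return out


def update_thesaurus(thesaurus: Thesaurus, resolutions: Iterable[SynonymEntry]) -> Thesaurus:
    """Add newly confirmed pairs; duplicate identical entries are no-ops and
    a conflicting standard for an existing (synonym, type) raises."""
    merged = Thesaurus(entries=dict(thesaurus.entries))
    for entry in resolutions:
        merged.add(entry)
    return merged


# ---------------------------------------------------------------------------
# pipeline-facing facade
# ---------------------------------------------------------------------------

class Standardizer:
    """Per-span naming policy used by the extraction pipeline.

    Tongue and pulse entities go through element decomposition (falling back
    to the thesaurus, then to the verbatim surface); herbs go through state-
    aware normalization; everything else through plain thesaurus lookup.
    Unresolved surfaces are collected in :attr:`unresolved` for the human-
    triage report.
    """

    def __init__(
        self,
        thesaurus: Thesaurus | None = None,
        element_lexicons: dict[str, ElementLexicon] | None = None,
    ) -> None:
        self.thesaurus = thesaurus or Thesaurus()
        self.element_lexicons = element_lexicons or {}
        self.unresolved: set[tuple[str, str]] = set()
        #: (surface -> standard) resolutions observed, for thesaurus updates
        self.resolutions: set[SynonymEntry] = set()

    _ELEMENT_TYPE_KEY = {"tongue_manifestation": "tongue", "pulse_condition": "pulse"}

    def name(self, span: EntitySpan) -> str:
        surface, etype = span.surface, span.entity_type
        std, resolved = standardize(surface, etype, self.thesaurus)
        if not resolved and etype in self._ELEMENT_TYPE_KEY:
            lex = self.element_lexicons.get(self._ELEMENT_TYPE_KEY[etype])
            if lex is not None:
                std, resolved = decompose_recompose(surface, lex)
        if not resolved and etype == "herb":
            std, resolved = herb_state_normalize(surface, self.thesaurus)
        if resolved:
            if std != surface:
                self.resolutions.add(SynonymEntry(surface, std, etype))
        else:
            self.unresolved.add((surface, etype))
        return std

    def __call__(self, span: EntitySpan) -> str:
        return self.name(span)

    def write_unresolved_report(self, path: str | Path) -> None:
        lines = [f"{s}\t{t}" for s, t in sorted(self.unresolved)]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
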