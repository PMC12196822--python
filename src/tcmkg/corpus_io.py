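"""Corpus I/O: annotated articles, gazetteer auto-annotation, metadata joins.

Articles carry raw text plus typed entity mentions anchored by character
offsets.  Offsets are 0-based, half-open, counted in Unicode code points, so
slicing is unambiguous for CJK text.  Two on-disk formats are supported:

* JSON Lines — one article per line with keys ``article_id``, ``book``,
  ``text``, ``dynasty``, ``year`` and ``spans`` (each span a dict with
  ``type``, ``start``, ``end``, ``surface``);
* standoff — a ``.txt`` file with the raw text and a sibling ``.ann`` file
  with one ``T<i>\\t<TYPE> <start> <end>\\t<surface>`` line per mention.

Dictionary auto-annotation follows leftmost-longest tiling: scanning left to
right, at each position the longest matching gazetteer term wins and the scan
resumes after it.  Regular-expression rules run afterwards on text not
already covered by a dictionary hit.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "EntitySpan",
    "AnnotatedArticle",
    "Gazetteer",
    "BookInfoRecord",
    "PhysicianRecord",
    "CorpusError",
    "SpanValidationError",
    "read_annotated",
    "write_annotated",
    "read_standoff",
    "write_standoff",
    "auto_annotate",
    "assign_article_ids",
    "load_gazetteer",
    "load_book_table",
    "load_physician_table",
    "join_book_metadata",
]


class CorpusError(Exception):
    """Malformed corpus input."""


class SpanValidationError(CorpusError):
    """A span violates offset/ordering/overlap invariants."""


@dataclass(frozen=True)
class Article:
    article_id: str
    source_book_title: str
    text: str
    dynasty: str | None = None
    year: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"article {self.article_id!r}: empty text")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed mention: ``surface == text[start:end]``."""

    start: int
    end: int
    entity_type: str = field(compare=False)
    surface: str = field(compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SpanValidationError(
                f"invalid offsets [{self.start}, {self.end}) for {self.surface!r}"
            )


@dataclass(frozen=True)
class AnnotatedArticle:
    article: Article
    spans: tuple[EntitySpan, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", tuple(self.spans))
        validate_spans(self.article, self.spans)

    @property
    def text(self) -> str:
        return self.article.text

    @property
    def article_id(self) -> str:
        return self.article.article_id


def validate_spans(article: Article, spans: Sequence[EntitySpan]) -> None:
    text = article.text
    prev_end = 0
    prev = None
    for sp in spans:
        if sp.end > len(text):
            raise SpanValidationError(
                f"article {article.article_id!r}: span [{sp.start}, {sp.end}) "
                f"exceeds text length {len(text)}"
            )
        if sp.start < prev_end:
            raise SpanValidationError(
                f"article {article.article_id!r}: span [{sp.start}, {sp.end}) "
                f"overlaps or precedes span ending at {prev_end} "
                f"({prev.surface!r} / {sp.surface!r})"
            )
        if text[sp.start : sp.end] != sp.surface:
            raise SpanValidationError(
                f"article {article.article_id!r}: surface {sp.surface!r} != "
                f"text[{sp.start}:{sp.end}] == {text[sp.start:sp.end]!r}"
            )
        prev_end = sp.end
        prev = sp


# ---------------------------------------------------------------------------
# JSON Lines format
# ---------------------------------------------------------------------------

def _span_to_dict(sp: EntitySpan) -> dict:
    return {"type": sp.entity_type, "start": sp.start, "end": sp.end, "surface": sp.surface}


def _article_to_dict(a: AnnotatedArticle) -> dict:
    d = {
        "article_id": a.article.article_id,
        "book": a.article.source_book_title,
        "text": a.article.text,
        "spans": [_span_to_dict(s) for s in a.spans],
    }
    if a.article.dynasty is not None:
        d["dynasty"] = a.article.dynasty
    if a.article.year is not None:
        d["year"] = a.article.year
    return d


def _article_from_dict(d: dict) -> AnnotatedArticle:
    art = Article(
        article_id=str(d["article_id"]),
        source_book_title=str(d.get("book", "")),
        text=d["text"],
        dynasty=d.get("dynasty"),
        year=d.get("year"),
    )
    spans = tuple(
        EntitySpan(
            start=int(s["start"]),
            end=int(s["end"]),
            entity_type=str(s["type"]),
            surface=str(s["surface"]),
        )
        for s in d.get("spans", [])
    )
    return AnnotatedArticle(article=art, spans=spans)


def read_annotated(path: str | Path) -> list[AnnotatedArticle]:
    """Read a JSON Lines annotated corpus, validating every span."""
    out: list[AnnotatedArticle] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            out.append(_article_from_dict(d))
    seen: set[str] = set()
    for a in out:
        if a.article_id in seen:
            raise CorpusError(f"duplicate article_id {a.article_id!r} in {path}")
        seen.add(a.article_id)
    return out


def write_annotated(articles: Iterable[AnnotatedArticle], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(json.dumps(_article_to_dict(a), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Standoff (.txt + .ann) format
# ---------------------------------------------------------------------------

_ANN_LINE = re.compile(r"^T\d+\t(?P<type>\S+) (?P<start>\d+) (?P<end>\d+)\t(?P<surface>.*)$")


def read_standoff(txt_path: str | Path, ann_path: str | Path | None = None,
                  article_id: str | None = None, book: str = "") -> AnnotatedArticle:
    txt_path = Path(txt_path)
    if ann_path is None:
        ann_path = txt_path.with_suffix(".ann")
    text = txt_path.read_text(encoding="utf-8")
    spans = []
    for lineno, line in enumerate(Path(ann_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        m = _ANN_LINE.match(line)
        if m is None:
            raise CorpusError(f"{ann_path}:{lineno}: cannot parse annotation line {line!r}")
        spans.append(
            EntitySpan(
                start=int(m["start"]), end=int(m["end"]),
                entity_type=m["type"], surface=m["surface"],
            )
        )
    spans.sort()
    art = Article(article_id=article_id or txt_path.stem, source_book_title=book, text=text)
    return AnnotatedArticle(article=art, spans=tuple(spans))


def write_standoff(article: AnnotatedArticle, txt_path: str | Path,
                   ann_path: str | Path | None = None) -> None:
    txt_path = Path(txt_path)
    if ann_path is None:
        ann_path = txt_path.with_suffix(".ann")
    txt_path.write_text(article.text, encoding="utf-8")
    lines = [
        f"T{i}\t{sp.entity_type} {sp.start} {sp.end}\t{sp.surface}"
        for i, sp in enumerate(article.spans, start=1)
    ]
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Gazetteer auto-annotation
# ---------------------------------------------------------------------------

@dataclass
class Gazetteer:
    """Dictionary terms plus optional regex rules, each mapped to a type."""

    entries: dict[str, str] = field(default_factory=dict)
    regex_rules: list[tuple[re.Pattern, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for term in self.entries:
            if not term:
                raise CorpusError("gazetteer contains an empty term")
        compiled = []
        for pat, etype in self.regex_rules:
            if isinstance(pat, str):
                try:
                    pat = re.compile(pat)
                except re.error as exc:
                    raise CorpusError(f"gazetteer regex {pat!r} does not compile: {exc}") from exc
            compiled.append((pat, etype))
        self.regex_rules = compiled


def load_gazetteer(path: str | Path, rules_path: str | Path | None = None) -> Gazetteer:
    """Load ``term<TAB>type`` TSV, optionally plus ``pattern<TAB>type`` rules."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusError(f"{path}:{lineno}: expected 'term<TAB>type', got {line!r}")
        entries[parts[0]] = parts[1]
    rules: list[tuple[re.Pattern, str]] = []
    if rules_path is not None:
        for lineno, line in enumerate(Path(rules_path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusError(f"{rules_path}:{lineno}: expected 'pattern<TAB>type'")
            rules.append((parts[0], parts[1]))
    return Gazetteer(entries=entries, regex_rules=rules)


def _dictionary_tile(text: str, entries: dict[str, str]) -> list[EntitySpan]:
    # leftmost-longest: at each position take the longest matching term,
    # then resume after it; no overlaps by construction
    if not entries:
        return []
    max_len = max(len(t) for t in entries)
    spans: list[EntitySpan] = []
    i, n = 0, len(text)
    while i < n:
        best = 0
        best_type = ""
        upper = min(max_len, n - i)
        for L in range(upper, 0, -1):
            cand = text[i : i + L]
            if cand in entries:
                best, best_type = L, entries[cand]
                break
        if best:
            spans.append(EntitySpan(start=i, end=i + best, entity_type=best_type,
                                    surface=text[i : i + best]))
            i += best
        else:
            i += 1
    return spans


def auto_annotate(article: Article, gaz: Gazetteer) -> AnnotatedArticle:
    """Annotate by dictionary tiling, then regex rules on uncovered text."""
    spans = _dictionary_tile(article.text, gaz.entries)
    covered = [(s.start, s.end) for s in spans]

    def overlaps(a: int, b: int) -> bool:
        return any(a < e and s < b for s, e in covered)

    for pat, etype in gaz.regex_rules:
        for m in pat.finditer(article.text):
            if m.start() == m.end() or overlaps(m.start(), m.end()):
                continue
            spans.append(EntitySpan(start=m.start(), end=m.end(),
                                    entity_type=etype, surface=m.group(0)))
            covered.append((m.start(), m.end()))
    spans.sort()
    return AnnotatedArticle(article=article, spans=tuple(spans))


# ---------------------------------------------------------------------------
# Article IDs and book metadata
# ---------------------------------------------------------------------------

def assign_article_ids(
    corpus: Sequence[AnnotatedArticle], prefix: str = "A", width: int = 6,
    keep_ids: bool = False,
) -> list[AnnotatedArticle]:
    """Assign sequential zero-padded IDs in input order.

    With ``keep_ids=True`` articles whose id is already non-empty are left
    untouched (idempotent re-run).
    """
    out: list[AnnotatedArticle] = []
    for i, a in enumerate(corpus, start=1):
        if keep_ids and a.article.article_id:
            out.append(a)
            continue
        new_id = f"{prefix}{i:0{width}d}"
        out.append(AnnotatedArticle(article=replace(a.article, article_id=new_id),
                                    spans=a.spans))
    return out


@dataclass(frozen=True)
class BookInfoRecord:
    title: str
    dynasty: str = ""
    year: str = ""
    author: str = ""

    def __post_init__(self) -> None:
        if not self.title:
            raise CorpusError("book record with empty title")


@dataclass(frozen=True)
class PhysicianRecord:
    name: str
    aliases: tuple[str, ...] = ()
    dynasty: str = ""
    places: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise CorpusError("physician record with empty name")
        object.__setattr__(self, "aliases", tuple(self.aliases))
        object.__setattr__(self, "places", tuple(self.places))


def _read_tsv(path: str | Path, ncols: int, what: str) -> Iterator[list[str]]:
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < ncols:
            parts += [""] * (ncols - len(parts))
        yield parts[:ncols]


def load_book_table(path: str | Path) -> dict[str, BookInfoRecord]:
    """TSV ``title<TAB>dynasty<TAB>year<TAB>author``; titles must be unique."""
    out: dict[str, BookInfoRecord] = {}
    for title, dynasty, year, author in _read_tsv(path, 4, "book"):
        key = _norm_title(title)
        if key in out:
            raise CorpusError(f"duplicate book title {title!r} in {path}")
        out[key] = BookInfoRecord(title=title, dynasty=dynasty, year=year, author=author)
    return out


def load_physician_table(path: str | Path) -> dict[str, PhysicianRecord]:
    """TSV ``name<TAB>aliases(;)<TAB>dynasty<TAB>places(;)``; names unique."""
    out: dict[str, PhysicianRecord] = {}
    for name, aliases, dynasty, places in _read_tsv(path, 4, "physician"):
        if name in out:
            raise CorpusError(f"duplicate physician name {name!r} in {path}")
        out[name] = PhysicianRecord(
            name=name,
            aliases=tuple(a for a in aliases.split(";") if a),
            dynasty=dynasty,
            places=tuple(p for p in places.split(";") if p),
        )
    return out


def _norm_title(title: str) -> str:
    return "".join(title.split())


def join_book_metadata(article: Article, books: dict[str, BookInfoRecord]) -> Article:
    """Fill dynasty/year from the book table by exact (whitespace-normalized)
    title match; unmatched titles leave the fields empty and log a warning."""
    rec = books.get(_norm_title(article.source_book_title))
    if rec is None:
        logger.warning(
            "article %s: source book %r not found in book table",
            article.article_id, article.source_book_title,
        )
        return article
    return replace(article, dynasty=rec.dynasty or article.dynasty,
                   year=rec.year or article.year)
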