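"""Stage 1 of progressive relation extraction: combination detection.

Three kinds of combinations are detected from the ordered entity spans of a
single article:

* **same-type combinations** — maximal runs of two or more contiguous
  entities of the same qualifying type (mechanisms, therapeutic principles,
  or the mixed symptom-and-sign group of symptom / tongue / pulse entities);
* **joint-formula combinations** — a basic formula (or herb group) together
  with keyword-triggered joined formulas, added herbs and removed herbs,
  each modification carrying the nearest qualifying basis;
* **differentiation-and-treatment (DT) combinations** — greedy left-to-right
  filling of the four process slots (disease/sign, cause-and-mechanism,
  therapeutic principle, remedy) under the element-uniqueness principle:
  a repeated slot closes the current combination and seeds a new one.

"Contiguous" means the text between two spans is at most ``max_gap``
characters long and consists only of delimiter punctuation or a listed
conjunction word.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .corpus_io import EntitySpan

logger = logging.getLogger(__name__)

__all__ = [
    "Stage1Config",
    "KeywordLexicon",
    "load_lexicon",
    "load_default_lexicon",
    "SameTypeCombination",
    "ModificationGroup",
    "JointFormulaCombination",
    "DTCombination",
    "detect_same_type",
    "detect_joint_formula",
    "attach_bases",
    "detect_dt",
    "SIGN_TYPES",
    "COOCCURRENCE_TYPES",
    "BASIS_TYPES",
    "DT_SLOTS",
]

#: diagnostic sign types that mix in one symptom-and-sign combination
SIGN_TYPES = frozenset({"symptom", "tongue_manifestation", "pulse_condition"})

#: the five types that participate in same-type co-occurrence combinations
COOCCURRENCE_TYPES = SIGN_TYPES | {"cause_and_mechanism", "therapeutic_principle_and_method"}

#: types that may serve as the basis of a formula modification
BASIS_TYPES = SIGN_TYPES | {"disease", "cause_and_mechanism", "therapeutic_principle_and_method"}

DT_SLOTS = ("disease_or_sign", "cause_mechanism", "principle_method", "formula_or_herb")

_SLOT_OF_TYPE = {
    "disease": "disease_or_sign",
    "symptom": "disease_or_sign",
    "tongue_manifestation": "disease_or_sign",
    "pulse_condition": "disease_or_sign",
    "cause_and_mechanism": "cause_mechanism",
    "therapeutic_principle_and_method": "principle_method",
    "formula": "formula_or_herb",
    "herb": "formula_or_herb",
}


@dataclass
class KeywordLexicon:
    add_keywords: list[str] = field(default_factory=list)
    remove_keywords: list[str] = field(default_factory=list)
    join_keywords: list[str] = field(default_factory=list)
    replace_patterns: list[re.Pattern] = field(default_factory=list)
    delimiters: str = "，。、；：,;:. \t"
    conjunctions: list[str] = field(default_factory=list)
    dosage_pattern: re.Pattern | None = None

    def __post_init__(self) -> None:
        self.replace_patterns = [
            re.compile(p) if isinstance(p, str) else p for p in self.replace_patterns
        ]
        if isinstance(self.dosage_pattern, str):
            self.dosage_pattern = re.compile(self.dosage_pattern)


def load_lexicon(path: str | Path) -> KeywordLexicon:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return KeywordLexicon(
        add_keywords=list(cfg.get("add_keywords", [])),
        remove_keywords=list(cfg.get("remove_keywords", [])),
        join_keywords=list(cfg.get("join_keywords", [])),
        replace_patterns=list(cfg.get("replace_patterns", [])),
        delimiters=str(cfg.get("delimiters", "，。、；：,;:. \t")),
        conjunctions=list(cfg.get("conjunctions", [])),
        dosage_pattern=cfg.get("dosage_pattern"),
    )


def load_default_lexicon() -> KeywordLexicon:
    text = resources.files("tcmkg.data").joinpath("default_lexicon.yaml").read_text("utf-8")
    cfg = yaml.safe_load(text)
    return KeywordLexicon(
        add_keywords=cfg["add_keywords"],
        remove_keywords=cfg["remove_keywords"],
        join_keywords=cfg["join_keywords"],
        replace_patterns=cfg["replace_patterns"],
        delimiters=cfg["delimiters"],
        conjunctions=cfg["conjunctions"],
        dosage_pattern=cfg["dosage_pattern"],
    )


@dataclass
class Stage1Config:
    """Tunable distances, in Unicode code points."""

    max_gap: int = 6          # longest permissible gap inside a combination
    keyword_window: int = 8   # how far before a group a trigger keyword may sit
    basis_window: int = 30    # search radius for a modification basis
    lexicon: KeywordLexicon = field(default_factory=load_default_lexicon)


# ---------------------------------------------------------------------------
# combination data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SameTypeCombination:
    """A contiguous run of >=2 same-group entities.

    ``entity_type`` is the group key: the shared type, or ``symptom_sign``
    for the mixed symptom / tongue / pulse variant.
    """

    entity_type: str
    members: tuple[EntitySpan, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ValueError("a combination needs at least two members")

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end


#: a basis is a single span or a whole same-type combination
Basis = Union[EntitySpan, SameTypeCombination, None]


@dataclass
class ModificationGroup:
    """One add / remove / join element of a joint-formula combination."""

    kind: str  # "add" | "remove" | "join"
    spans: tuple[EntitySpan, ...]
    basis: Basis = None

    def __post_init__(self) -> None:
        self.spans = tuple(self.spans)

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end


@dataclass
class JointFormulaCombination:
    """Composite treatment regimen built around one basic formula.

    ``basic_formula`` is either a single formula span or a tuple of herb
    spans (the herb-group case).  Exactly one basic element exists; the
    modification groups may repeat.
    """

    basic_formula: EntitySpan | tuple[EntitySpan, ...]
    joined: list[ModificationGroup] = field(default_factory=list)
    added: list[ModificationGroup] = field(default_factory=list)
    removed: list[ModificationGroup] = field(default_factory=list)
    dosages: dict[EntitySpan, str] = field(default_factory=dict)

    @property
    def basic_is_group(self) -> bool:
        return isinstance(self.basic_formula, tuple)

    @property
    def basic_spans(self) -> tuple[EntitySpan, ...]:
        if self.basic_is_group:
            return self.basic_formula
        return (self.basic_formula,)

    @property
    def groups(self) -> list[ModificationGroup]:
        return self.joined + self.added + self.removed

    @property
    def all_spans(self) -> tuple[EntitySpan, ...]:
        out = list(self.basic_spans)
        for g in self.groups:
            out.extend(g.spans)
        return tuple(sorted(out))

    @property
    def start(self) -> int:
        return self.all_spans[0].start

    @property
    def end(self) -> int:
        return self.all_spans[-1].end


#: an atomic DT element
Element = Union[EntitySpan, SameTypeCombination, JointFormulaCombination]


@dataclass
class DTCombination:
    """One differentiation-and-treatment episode: up to four filled slots."""

    slots: dict[str, Element] = field(default_factory=dict)

    @property
    def n_filled(self) -> int:
        return len(self.slots)

    def member_spans(self) -> list[EntitySpan]:
        out: list[EntitySpan] = []
        for el in self.slots.values():
            out.extend(element_spans(el))
        return sorted(out)


def element_start(el: Element) -> int:
    return el.start


def element_spans(el: Element) -> tuple[EntitySpan, ...]:
    if isinstance(el, EntitySpan):
        return (el,)
    if isinstance(el, SameTypeCombination):
        return el.members
    return el.all_spans


# ---------------------------------------------------------------------------
# same-type combination detection
# ---------------------------------------------------------------------------

def _group_key(entity_type: str) -> str | None:
    if entity_type in SIGN_TYPES:
        return "symptom_sign"
    if entity_type in COOCCURRENCE_TYPES:
        return entity_type
    return None


def _gap_ok(text: str, a: EntitySpan, b: EntitySpan, cfg: Stage1Config) -> bool:
    gap = text[a.end : b.start]
    if len(gap) > cfg.max_gap:
        return False
    lex = cfg.lexicon
    residue = gap
    # peel dosage expressions (they legitimately sit between herb mentions)
    if lex.dosage_pattern is not None:
        residue = lex.dosage_pattern.sub("", residue)
    residue = "".join(ch for ch in residue if ch not in lex.delimiters)
    return residue == "" or residue in lex.conjunctions


def _check_sorted(spans: Sequence[EntitySpan]) -> None:
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValueError(
                f"spans must be sorted and non-overlapping: "
                f"[{a.start},{a.end}) then [{b.start},{b.end})"
            )


def detect_same_type(
    spans: Sequence[EntitySpan], text: str, cfg: Stage1Config | None = None
) -> list[SameTypeCombination]:
    """Maximal contiguous runs of >=2 qualifying same-group spans.

    Only the five co-occurrence types participate; symptom, tongue and pulse
    entities mix freely in one symptom-and-sign combination.  A non-member
    span between two candidates always breaks the run, as does a gap longer
    than ``max_gap`` or containing non-delimiter text.
    """
    cfg = cfg or Stage1Config()
    _check_sorted(spans)
    out: list[SameTypeCombination] = []
    run: list[EntitySpan] = []
    run_key: str | None = None

    def flush() -> None:
        nonlocal run, run_key
        if run_key is not None and len(run) >= 2:
            out.append(SameTypeCombination(entity_type=run_key, members=tuple(run)))
        run, run_key = [], None

    for i, sp in enumerate(spans):
        key = _group_key(sp.entity_type)
        if key is None:
            flush()
            continue
        if (
            run_key == key
            and run
            and _gap_ok(text, run[-1], sp, cfg)
            and spans[i - 1] is run[-1]  # no foreign span in between
        ):
            run.append(sp)
        else:
            flush()
            run, run_key = [sp], key
    flush()
    return out


# ---------------------------------------------------------------------------
# joint-formula combination detection
# ---------------------------------------------------------------------------

def _keyword_before(text: str, pos: int, keywords: Iterable[str], cfg: Stage1Config) -> bool:
    window = text[max(0, pos - cfg.keyword_window) : pos]
    window = window.rstrip("".join(cfg.lexicon.delimiters) or None)
    return any(window.endswith(k) for k in keywords if k)


def _dosage_after(text: str, span: EntitySpan, cfg: Stage1Config) -> str | None:
    pat = cfg.lexicon.dosage_pattern
    if pat is None:
        return None
    m = pat.match(text, span.end)
    return m.group(0) if m else None


def _herb_groups(spans: Sequence[EntitySpan], text: str, cfg: Stage1Config
                 ) -> list[list[EntitySpan]]:
    groups: list[list[EntitySpan]] = []
    cur: list[EntitySpan] = []
    prev_idx = -2
    for i, sp in enumerate(spans):
        if sp.entity_type != "herb":
            if cur:
                groups.append(cur)
                cur = []
            continue
        if cur and prev_idx == i - 1 and _gap_ok(text, cur[-1], sp, cfg):
            cur.append(sp)
        else:
            if cur:
                groups.append(cur)
            cur = [sp]
        prev_idx = i
    if cur:
        groups.append(cur)
    return groups


def _replace_marks(text: str, cfg: Stage1Config) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Character ranges captured by replacement constructs.

    Returns (added ranges, removed ranges): group 1 of each pattern holds the
    incoming herbs, group 2 the outgoing ones.
    """
    added: list[tuple[int, int]] = []
    removed: list[tuple[int, int]] = []
    for pat in cfg.lexicon.replace_patterns:
        if pat.groups < 2:
            continue
        for m in pat.finditer(text):
            added.append(m.span(1))
            removed.append(m.span(2))
    return added, removed


def _in_ranges(sp: EntitySpan, ranges: list[tuple[int, int]]) -> bool:
    return any(a <= sp.start and sp.end <= b for a, b in ranges)


def detect_joint_formula(
    spans: Sequence[EntitySpan], text: str, cfg: Stage1Config | None = None
) -> list[JointFormulaCombination]:
    """Detect composite treatment regimens.

    The basic formula is the first formula span (or first contiguous herb
    group) of an episode.  Subsequent formula spans preceded by a joining
    keyword become ``joined``; herb groups preceded by addition / removal
    keywords become ``added`` / ``removed``; replacement constructs split
    into one addition and one removal.  A virtual combination is only worth
    emitting when some modification exists or the basic element is a herb
    group of two or more herbs — a lone formula mention stays a plain entity.
    """
    cfg = cfg or Stage1Config()
    _check_sorted(spans)
    rep_add, rep_rem = _replace_marks(text, cfg)

    # build the ordered sequence of treatment elements
    items: list[tuple[str, object]] = []  # ("formula", span) | ("herbs", [spans])
    hg = {id(g[0]): g for g in _herb_groups(spans, text, cfg)}
    for sp in spans:
        if sp.entity_type == "formula":
            items.append(("formula", sp))
        elif sp.entity_type == "herb" and id(sp) in hg:
            items.append(("herbs", hg[id(sp)]))

    out: list[JointFormulaCombination] = []
    cur: JointFormulaCombination | None = None
    cur_has_mod = False

    def close() -> None:
        nonlocal cur, cur_has_mod
        if cur is not None and (
            cur_has_mod or (cur.basic_is_group and len(cur.basic_formula) >= 2)
        ):
            out.append(cur)
        cur, cur_has_mod = None, False

    def capture_doses(jf: JointFormulaCombination, group: Sequence[EntitySpan]) -> None:
        for sp in group:
            d = _dosage_after(text, sp, cfg)
            if d is not None:
                jf.dosages[sp] = d

    lex = cfg.lexicon
    for kind, payload in items:
        if kind == "formula":
            sp = payload
            if cur is not None and _keyword_before(text, sp.start, lex.join_keywords, cfg):
                cur.joined.append(ModificationGroup(kind="join", spans=(sp,)))
                cur_has_mod = True
            else:
                close()
                cur = JointFormulaCombination(basic_formula=sp)
        else:
            group: list[EntitySpan] = list(payload)
            marked_add = [s for s in group if _in_ranges(s, rep_add)]
            marked_rem = [s for s in group if _in_ranges(s, rep_rem)]
            plain = [s for s in group if s not in marked_add and s not in marked_rem]
            if marked_add or marked_rem:
                if cur is None:
                    logger.warning(
                        "replacement construct at offset %d has no preceding "
                        "basic formula; skipped", group[0].start,
                    )
                else:
                    if marked_add:
                        cur.added.append(ModificationGroup(kind="add", spans=tuple(marked_add)))
                        capture_doses(cur, marked_add)
                    if marked_rem:
                        cur.removed.append(ModificationGroup(kind="remove", spans=tuple(marked_rem)))
                        capture_doses(cur, marked_rem)
                    cur_has_mod = True
                group = plain
                if not group:
                    continue
            pos = group[0].start
            if cur is not None and _keyword_before(text, pos, lex.add_keywords, cfg):
                cur.added.append(ModificationGroup(kind="add", spans=tuple(group)))
                capture_doses(cur, group)
                cur_has_mod = True
            elif _keyword_before(text, pos, lex.remove_keywords, cfg):
                if cur is None:
                    logger.warning(
                        "removal keyword before offset %d has no preceding "
                        "basic formula; group skipped", pos,
                    )
                else:
                    cur.removed.append(ModificationGroup(kind="remove", spans=tuple(group)))
                    capture_doses(cur, group)
                    cur_has_mod = True
            elif cur is None:
                cur = JointFormulaCombination(basic_formula=tuple(group))
                capture_doses(cur, group)
            else:
                close()
                cur = JointFormulaCombination(basic_formula=tuple(group))
                capture_doses(cur, group)
    close()
    return out


def attach_bases(
    jf: JointFormulaCombination,
    spans: Sequence[EntitySpan],
    combos: Sequence[SameTypeCombination],
    cfg: Stage1Config | None = None,
) -> JointFormulaCombination:
    """Assign each modification group its nearest qualifying basis.

    Candidates are basis-type entities (or whole same-type combinations) on
    either side of the group within ``basis_window`` code points; ties in
    distance favour the preceding side.  Spans belonging to the combination
    itself never serve as a basis.  Mutates and returns ``jf``.
    """
    cfg = cfg or Stage1Config()
    own = set((s.start, s.end) for s in jf.all_spans)
    in_combo: dict[tuple[int, int], SameTypeCombination] = {}
    for c in combos:
        for m in c.members:
            in_combo[(m.start, m.end)] = c

    candidates: list[tuple[int, int, Basis]] = []  # (start, end, element)
    seen_combos: set[int] = set()
    for sp in spans:
        if sp.entity_type not in BASIS_TYPES or (sp.start, sp.end) in own:
            continue
        c = in_combo.get((sp.start, sp.end))
        if c is not None:
            if id(c) not in seen_combos:
                candidates.append((c.start, c.end, c))
                seen_combos.add(id(c))
        else:
            candidates.append((sp.start, sp.end, sp))

    for group in jf.groups:
        best: Basis = None
        best_key: tuple[int, int] | None = None
        for start, end, el in candidates:
            if end <= group.start:
                dist, side = group.start - end, 0  # preceding wins ties
            elif start >= group.end:
                dist, side = start - group.end, 1
            else:
                continue
            if dist > cfg.basis_window:
                continue
            key = (dist, side)
            if best_key is None or key < best_key:
                best, best_key = el, key
        group.basis = best
    return jf


# ---------------------------------------------------------------------------
# differentiation-and-treatment combination detection
# ---------------------------------------------------------------------------

def detect_dt(
    spans: Sequence[EntitySpan],
    combos: Sequence[SameTypeCombination] = (),
    jfs: Sequence[JointFormulaCombination] = (),
) -> list[DTCombination]:
    """Greedy slot filling over document-ordered elements.

    Each same-type combination and each joint-formula combination is one
    atomic element.  An element fills its slot if empty; if the slot is
    already taken, the open combination is closed (emitted when at least two
    slots are filled) and a fresh one starts with the violating element.
    """
    _check_sorted(spans)
    consumed: set[tuple[int, int]] = set()
    elements: list[tuple[int, str, Element]] = []

    for jf in jfs:
        for s in jf.all_spans:
            consumed.add((s.start, s.end))
        elements.append((jf.start, "formula_or_herb", jf))
    for c in combos:
        if any((m.start, m.end) in consumed for m in c.members):
            continue
        slot = _SLOT_OF_TYPE.get(c.members[0].entity_type)
        if slot is None:
            continue
        for m in c.members:
            consumed.add((m.start, m.end))
        elements.append((c.start, slot, c))
    for sp in spans:
        if (sp.start, sp.end) in consumed:
            continue
        slot = _SLOT_OF_TYPE.get(sp.entity_type)
        if slot is not None:
            elements.append((sp.start, slot, sp))

    elements.sort(key=lambda t: t[0])

    out: list[DTCombination] = []
    cur: dict[str, Element] = {}

    def close() -> None:
        nonlocal cur
        if len(cur) >= 2:
            out.append(DTCombination(slots=dict(cur)))
        cur = {}

    for _, slot, el in elements:
        if slot in cur:
            close()
        cur[slot] = el
    close()
    return out
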