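"""Seeded synthetic-corpus generator with a constructive triple oracle.

Each generated pseudo-article instantiates one structural template the
extractor targets — parallel sign–cause pairs, full or partial
differentiation-and-treatment processes, joint-formula episodes
(additions, removals, replacements, joined formulas, herb-group basics),
or auxiliary-entity contexts — and the generator derives the *correct*
stage-1/stage-2 output constructively from the template structure while it
writes the text.  The oracle is therefore independent of the extraction
code: it never calls the detector or the schema helpers, but re-states the
expected relations from the template's own bookkeeping.

Entity surfaces are script-agnostic placeholder tokens (``SYM01``,
``HRB03`` …): the extraction engine operates on spans plus keyword
lexicons, not on any particular language.  Delimiters and trigger keywords
come from the default lexicon, so generated corpora run through the
pipeline unconfigured.

Same seed, same spec ⇒ byte-identical corpus and oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import AnnotatedArticle, Article, EntitySpan
from .instantiate import Triple

__all__ = ["FixtureSpec", "FixtureCorpus", "generate", "DEFAULT_MIX"]

DEFAULT_MIX = {
    "parallel_pairs": 0.25,
    "full_dt": 0.25,
    "partial_dt": 0.20,
    "joint_formula": 0.20,
    "auxiliary": 0.10,
}

_PREFIX = {
    "disease": "DIS", "symptom": "SYM", "tongue_manifestation": "TNG",
    "pulse_condition": "PUL", "cause_and_mechanism": "CAU",
    "therapeutic_principle_and_method": "TPM", "formula": "FML",
    "herb": "HRB", "time": "TIM", "physician": "DOC", "book_title": "BOK",
}

_DOSES = ["3g", "6g", "9g", "15g"]


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_articles: int = 20
    mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    vocab_size: int = 40  # distinct surfaces per entity type

    def __post_init__(self) -> None:
        if self.n_articles < 0:
            raise FixtureSpecError("n_articles must be >= 0")
        total = sum(self.mix.values())
        if self.mix and abs(total - 1.0) > 1e-9:
            raise FixtureSpecError(f"pattern-mix proportions must sum to 1, got {total}")
        unknown = set(self.mix) - set(DEFAULT_MIX)
        if unknown:
            raise FixtureSpecError(f"unknown pattern names: {sorted(unknown)}")


@dataclass
class FixtureCorpus:
    articles: list[AnnotatedArticle]
    oracle_triples: set[Triple]
    #: expected corpus-level category counts
    counts: dict

    @property
    def oracle_by_relation(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.oracle_triples:
            out[t.relation] = out.get(t.relation, 0) + 1
        return out


class _Builder:
    """Accumulates text + spans + the article's expected triples."""

    def __init__(self, aid: str) -> None:
        self.aid = aid
        self.parts: list[str] = []
        self.pos = 0
        self.spans: list[EntitySpan] = []
        self.triples: set[Triple] = set()
        self.n_virtual = 0
        self.n_dt = 0
        self.baseline_count: int | None = None

    def lit(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def ent(self, etype: str, surface: str) -> EntitySpan:
        sp = EntitySpan(start=self.pos, end=self.pos + len(surface),
                        entity_type=etype, surface=surface)
        self.spans.append(sp)
        self.lit(surface)
        return sp

    # oracle bookkeeping ---------------------------------------------------

    @staticmethod
    def nid(etype: str, name: str) -> str:
        return f"{etype}:{name}"

    def vid(self) -> str:
        self.n_virtual += 1
        return f"JF:{self.aid}:{self.n_virtual}"

    def expect(self, subj: str, rel: str, obj: str, dosage: str | None = None) -> None:
        attrs = (("dosage", dosage),) if dosage else ()
        self.triples.add(Triple(subject=subj, relation=rel, object=obj,
                                attributes=attrs, provenance=self.aid))

    def finish(self) -> AnnotatedArticle:
        # article-ID linkage: one edge to every distinct node of the article
        anode = self.nid("article_id", self.aid)
        targets = {self.nid(sp.entity_type, sp.surface) for sp in self.spans}
        targets.update(f"JF:{self.aid}:{k}" for k in range(1, self.n_virtual + 1))
        for node_id in sorted(targets):
            self.expect(anode, "article_id_is", node_id)
        art = Article(article_id=self.aid, source_book_title="synthetic corpus",
                      text="".join(self.parts))
        return AnnotatedArticle(article=art, spans=tuple(sorted(self.spans)))


class _Vocab:
    def __init__(self, rng: random.Random, size: int) -> None:
        self.rng = rng
        self.size = size
        self.used: dict[str, set[int]] = {}

    def fresh(self, etype: str, k: int = 1) -> list[str]:
        """k surfaces of one type, distinct within the current article."""
        used = self.used.setdefault(etype, set())
        free = [i for i in range(1, self.size + 1) if i not in used]
        picks = self.rng.sample(free, k)
        used.update(picks)
        return [f"{_PREFIX[etype]}{i:02d}" for i in picks]

    def reset_article(self) -> None:
        self.used.clear()


# ---------------------------------------------------------------------------
# templates — each writes text and records the expected triples
# ---------------------------------------------------------------------------

def _t_parallel_pairs(b: _Builder, v: _Vocab, rng: random.Random) -> None:
    k = rng.randint(2, 3)
    pulses = v.fresh("pulse_condition", k)
    causes = v.fresh("cause_and_mechanism", k)
    for pul, cau in zip(pulses, causes):
        b.ent("pulse_condition", pul)
        b.lit("，")
        b.ent("cause_and_mechanism", cau)
        b.lit("。")
        b.expect(b.nid("cause_and_mechanism", cau), "cause",
                 b.nid("pulse_condition", pul))
        b.n_dt += 1
    # the full-connection baseline links every mechanism to every pulse
    b.baseline_count = k * k


def _t_full_dt(b: _Builder, v: _Vocab, rng: random.Random) -> None:
    m = rng.randint(2, 3)
    syms = v.fresh("symptom", m)
    (cau,) = v.fresh("cause_and_mechanism")
    (tpm,) = v.fresh("therapeutic_principle_and_method")
    (fml,) = v.fresh("formula")
    for i, s in enumerate(syms):
        if i:
            b.lit("，")
        b.ent("symptom", s)
    b.lit("。")
    b.ent("cause_and_mechanism", cau)
    b.lit("。")
    b.ent("therapeutic_principle_and_method", tpm)
    b.lit("。")
    b.ent("formula", fml)
    b.lit("。")
    sym_ids = [b.nid("symptom", s) for s in syms]
    cau_id = b.nid("cause_and_mechanism", cau)
    tpm_id = b.nid("therapeutic_principle_and_method", tpm)
    fml_id = b.nid("formula", fml)
    for i in range(m):
        for j in range(i + 1, m):
            b.expect(sym_ids[i], "co_occurrence", sym_ids[j])
    for s_id in sym_ids:
        b.expect(cau_id, "cause", s_id)
        b.expect(tpm_id, "be_applicable_to", s_id)
        b.expect(fml_id, "treat", s_id)
    b.expect(tpm_id, "be_applicable_to", cau_id)
    b.expect(fml_id, "treat", cau_id)
    b.expect(tpm_id, "use", fml_id)
    b.n_dt += 1


def _t_partial_dt(b: _Builder, v: _Vocab, rng: random.Random) -> None:
    variant = rng.choice(["dis_cau", "cau_tpm", "tpm_fml", "lone"])
    if variant == "dis_cau":
        (dis,) = v.fresh("disease")
        (cau,) = v.fresh("cause_and_mechanism")
        b.ent("disease", dis); b.lit("。")
        b.ent("cause_and_mechanism", cau); b.lit("。")
        b.expect(b.nid("cause_and_mechanism", cau), "cause", b.nid("disease", dis))
        b.n_dt += 1
    elif variant == "cau_tpm":
        (cau,) = v.fresh("cause_and_mechanism")
        (tpm,) = v.fresh("therapeutic_principle_and_method")
        b.ent("cause_and_mechanism", cau); b.lit("。")
        b.ent("therapeutic_principle_and_method", tpm); b.lit("。")
        b.expect(b.nid("therapeutic_principle_and_method", tpm), "be_applicable_to",
                 b.nid("cause_and_mechanism", cau))
        b.n_dt += 1
    elif variant == "tpm_fml":
        (tpm,) = v.fresh("therapeutic_principle_and_method")
        (fml,) = v.fresh("formula")
        b.ent("therapeutic_principle_and_method", tpm); b.lit("。")
        b.ent("formula", fml); b.lit("。")
        b.expect(b.nid("therapeutic_principle_and_method", tpm), "use",
                 b.nid("formula", fml))
        b.n_dt += 1
    else:
        # a single process element never forms a combination
        (sym,) = v.fresh("symptom")
        b.ent("symptom", sym)
        b.lit("。")


def _t_joint_formula(b: _Builder, v: _Vocab, rng: random.Random) -> None:
    variant = rng.choice(["add", "remove", "join", "herb_group", "replace"])
    (cau,) = v.fresh("cause_and_mechanism")
    cau_id = b.nid("cause_and_mechanism", cau)
    b.ent("cause_and_mechanism", cau)
    b.lit("。")
    jf_id = b.vid()

    if variant == "herb_group":
        herbs = v.fresh("herb", rng.randint(2, 3))
        doses = [rng.choice(_DOSES) if rng.random() < 0.7 else None for _ in herbs]
        for i, (h, d) in enumerate(zip(herbs, doses)):
            if i:
                b.lit("，")
            b.ent("herb", h)
            if d:
                b.lit(d)
            b.expect(jf_id, "composition_of_basic_formula_is", b.nid("herb", h), dosage=d)
        b.lit("。")
    else:
        (fml,) = v.fresh("formula")
        b.ent("formula", fml)
        b.expect(jf_id, "basic_formula_is", b.nid("formula", fml))
        if variant == "join":
            (fml2,) = v.fresh("formula")
            b.lit("，JOIN ")
            b.ent("formula", fml2)
            b.lit("。")
            b.expect(jf_id, "add_formula_to_basic_formula", b.nid("formula", fml2))
            b.expect(jf_id, "basis_for_adding_formula", cau_id)
        elif variant == "replace":
            h_in, h_out = v.fresh("herb", 2)
            b.lit("，REPLACE ")
            b.ent("herb", h_in)
            b.lit(" FOR ")
            b.ent("herb", h_out)
            b.lit("。")
            b.expect(jf_id, "add_herb_to_basic_formula", b.nid("herb", h_in))
            b.expect(jf_id, "remove_herb_to_basic_formula", b.nid("herb", h_out))
            b.expect(jf_id, "basis_for_adding_herb", cau_id)
            b.expect(jf_id, "basis_for_removing_herb", cau_id)
        else:
            kw = "ADD" if variant == "add" else "REMOVE"
            rel = ("add_herb_to_basic_formula" if variant == "add"
                   else "remove_herb_to_basic_formula")
            basis_rel = ("basis_for_adding_herb" if variant == "add"
                         else "basis_for_removing_herb")
            herbs = v.fresh("herb", rng.randint(1, 2))
            b.lit(f"，{kw} ")
            for i, h in enumerate(herbs):
                if i:
                    b.lit("，")
                b.ent("herb", h)
                d = rng.choice(_DOSES) if rng.random() < 0.7 else None
                if d:
                    b.lit(d)
                b.expect(jf_id, rel, b.nid("herb", h), dosage=d)
            b.lit("。")
            b.expect(jf_id, basis_rel, cau_id)

    # the DT combination: mechanism + regimen (virtual node stands in)
    b.expect(jf_id, "treat", cau_id)
    b.n_dt += 1


def _t_auxiliary(b: _Builder, v: _Vocab, rng: random.Random) -> None:
    variant = rng.choice(["time", "physician", "book"])
    (dis,) = v.fresh("disease")
    (cau,) = v.fresh("cause_and_mechanism")
    dis_id, cau_id = b.nid("disease", dis), b.nid("cause_and_mechanism", cau)
    if variant == "time":
        (tim,) = v.fresh("time")
        b.ent("time", tim)
        b.lit("，")
        b.expect(b.nid("time", tim), "occurrence", dis_id)
    b.ent("disease", dis)
    b.lit("，")
    b.ent("cause_and_mechanism", cau)
    b.lit("。")
    b.expect(cau_id, "cause", dis_id)
    b.n_dt += 1
    if variant == "physician":
        (doc,) = v.fresh("physician")
        b.ent("physician", doc)
        b.lit("。")
        b.expect(b.nid("physician", doc), "discuss", dis_id)
        b.expect(b.nid("physician", doc), "discuss", cau_id)
    elif variant == "book":
        (bok,) = v.fresh("book_title")
        b.ent("book_title", bok)
        b.lit("。")
        b.expect(dis_id, "record_in", b.nid("book_title", bok))
        b.expect(cau_id, "record_in", b.nid("book_title", bok))


_TEMPLATES = {
    "parallel_pairs": _t_parallel_pairs,
    "full_dt": _t_full_dt,
    "partial_dt": _t_partial_dt,
    "joint_formula": _t_joint_formula,
    "auxiliary": _t_auxiliary,
}


def generate(spec: FixtureSpec) -> FixtureCorpus:
    """Generate an annotated corpus plus its constructive oracle."""
    rng = random.Random(spec.seed)
    vocab = _Vocab(rng, spec.vocab_size)
    names = sorted(spec.mix)
    weights = [spec.mix[n] for n in names]

    articles: list[AnnotatedArticle] = []
    oracle: set[Triple] = set()
    n_dt = n_virtual = 0
    baseline_counts: dict[str, int] = {}

    for i in range(1, spec.n_articles + 1):
        aid = f"A{i:06d}"
        template = rng.choices(names, weights=weights, k=1)[0] if names else "partial_dt"
        b = _Builder(aid)
        vocab.reset_article()
        _TEMPLATES[template](b, vocab, rng)
        articles.append(b.finish())
        oracle |= b.triples
        n_dt += b.n_dt
        n_virtual += b.n_virtual
        if b.baseline_count is not None:
            baseline_counts[aid] = b.baseline_count

    n_cooc = sum(1 for t in oracle if t.relation == "co_occurrence")
    n_virtual_rel = sum(
        1 for t in oracle
        if t.subject.startswith("JF:") or t.object.startswith("JF:")
    )
    node_ids = set()
    for t in oracle:
        node_ids.add(t.subject)
        node_ids.add(t.object)
    counts = {
        "n_articles": spec.n_articles,
        "n_dt_combinations": n_dt,
        "n_virtual_entities": n_virtual,
        "n_cooccurrence": n_cooc,
        "n_virtual_relationships": n_virtual_rel,
        "n_triples": len(oracle),
        "n_entities": len(node_ids),
        "baseline_counts_parallel_pairs": baseline_counts,
    }
    return FixtureCorpus(articles=articles, oracle_triples=oracle, counts=counts)
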