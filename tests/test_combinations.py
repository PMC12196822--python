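"""Stage-1 combination detection against brute-force oracles."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from tcmkg.combinations import (
    COOCCURRENCE_TYPES,
    DTCombination,
    JointFormulaCombination,
    SameTypeCombination,
    Stage1Config,
    attach_bases,
    detect_dt,
    detect_joint_formula,
    detect_same_type,
    element_spans,
    _group_key,
)
from tcmkg.corpus_io import EntitySpan

from conftest import make_article


# ---------------------------------------------------------------------------
# same-type combinations
# ---------------------------------------------------------------------------

class TestSameType:
    def test_three_adjacent_symptoms_form_one_combination(self, mk_article):
        a = mk_article([("symptom", "SYM01"), ("symptom", "SYM02"), ("symptom", "SYM03")])
        combos = detect_same_type(a.spans, a.text)
        assert len(combos) == 1
        assert len(combos[0].members) == 3
        assert combos[0].entity_type == "symptom_sign"

    def test_foreign_span_breaks_the_run(self, mk_article):
        a = mk_article([("symptom", "SYM01"), ("herb", "HRB01"), ("symptom", "SYM02")])
        assert detect_same_type(a.spans, a.text) == []

    def test_symptom_and_signs_mix(self, mk_article):
        a = mk_article([("symptom", "SYM01"), ("tongue_manifestation", "TNG01"),
                        ("pulse_condition", "PUL01")])
        combos = detect_same_type(a.spans, a.text)
        assert len(combos) == 1 and len(combos[0].members) == 3

    def test_mechanisms_do_not_mix_with_signs(self, mk_article):
        a = mk_article([("symptom", "SYM01"), ("cause_and_mechanism", "CAU01")])
        assert detect_same_type(a.spans, a.text) == []

    def test_wide_gap_breaks_the_run(self):
        text = "SYM01，，，，，，，，SYM02"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(13, 18, "symptom", "SYM02"))
        assert detect_same_type(spans, text) == []

    def test_non_delimiter_gap_breaks_the_run(self):
        text = "SYM01某些字SYM02"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(8, 13, "symptom", "SYM02"))
        assert detect_same_type(spans, text) == []

    def test_conjunction_word_allowed_in_gap(self):
        text = "SYM01及SYM02"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(6, 11, "symptom", "SYM02"))
        combos = detect_same_type(spans, text)
        assert len(combos) == 1 and len(combos[0].members) == 2

    def test_unsorted_input_rejected(self):
        spans = (EntitySpan(6, 11, "symptom", "SYM02"),
                 EntitySpan(0, 5, "symptom", "SYM01"))
        with pytest.raises(ValueError, match="sorted"):
            detect_same_type(spans, "SYM01，SYM02")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_maximal_run_oracle(self, data):
        """Randomized sequences equal an O(n^3) maximal-window oracle."""
        types = ["symptom", "tongue_manifestation", "pulse_condition",
                 "cause_and_mechanism", "therapeutic_principle_and_method",
                 "herb", "disease"]
        n = data.draw(st.integers(0, 14))
        seq = data.draw(st.lists(
            st.tuples(st.sampled_from(types), st.sampled_from(["，", "；；；；；；；", "文"])),
            min_size=n, max_size=n))
        # build text: token then its trailing gap
        pos, text, spans = 0, [], []
        for i, (etype, gap) in enumerate(seq):
            tok = f"T{i:02d}"
            spans.append(EntitySpan(pos, pos + len(tok), etype, tok))
            text.append(tok)
            pos += len(tok)
            text.append(gap)
            pos += len(gap)
        text = "".join(text)
        spans = tuple(spans)
        cfg = Stage1Config()

        def adjacent(i):
            a, b = spans[i], spans[i + 1]
            if _group_key(a.entity_type) != _group_key(b.entity_type):
                return False
            if _group_key(a.entity_type) is None:
                return False
            gap = text[a.end:b.start]
            return len(gap) <= cfg.max_gap and all(
                ch in cfg.lexicon.delimiters for ch in gap)

        expected = []
        i = 0
        m = len(spans)
        for lo in range(m):
            if _group_key(spans[lo].entity_type) is None:
                continue
            for hi in range(lo + 1, m):
                window_ok = all(adjacent(k) for k in range(lo, hi))
                maximal = window_ok and (lo == 0 or not adjacent(lo - 1)) \
                    and (hi == m - 1 or not adjacent(hi))
                if maximal:
                    expected.append((lo, hi))
        got = detect_same_type(spans, text, cfg)
        got_idx = [(spans.index(c.members[0]), spans.index(c.members[-1])) for c in got]
        assert got_idx == sorted(set(expected))


# ---------------------------------------------------------------------------
# joint-formula combinations
# ---------------------------------------------------------------------------

def _spans_text(article):
    return article.spans, article.text


class TestJointFormula:
    def test_formula_plus_added_herbs(self):
        text = "FML01，ADD HRB01，HRB02。"
        spans = (EntitySpan(0, 5, "formula", "FML01"),
                 EntitySpan(10, 15, "herb", "HRB01"),
                 EntitySpan(16, 21, "herb", "HRB02"))
        jfs = detect_joint_formula(spans, text)
        assert len(jfs) == 1
        jf = jfs[0]
        assert jf.basic_formula == spans[0]
        assert [s.surface for g in jf.added for s in g.spans] == ["HRB01", "HRB02"]
        assert jf.removed == [] and jf.joined == []

    def test_replacement_splits_into_add_and_remove(self):
        text = "FML01，REPLACE HRB01 FOR HRB02。"
        spans = (EntitySpan(0, 5, "formula", "FML01"),
                 EntitySpan(14, 19, "herb", "HRB01"),
                 EntitySpan(24, 29, "herb", "HRB02"))
        jf, = detect_joint_formula(spans, text)
        assert [s.surface for g in jf.added for s in g.spans] == ["HRB01"]
        assert [s.surface for g in jf.removed for s in g.spans] == ["HRB02"]

    def test_herb_group_becomes_basic_formula(self):
        text = "HRB01，HRB02，HRB03。"
        spans = (EntitySpan(0, 5, "herb", "HRB01"),
                 EntitySpan(6, 11, "herb", "HRB02"),
                 EntitySpan(12, 17, "herb", "HRB03"))
        jf, = detect_joint_formula(spans, text)
        assert jf.basic_is_group
        assert [s.surface for s in jf.basic_formula] == ["HRB01", "HRB02", "HRB03"]

    def test_lone_formula_is_not_a_combination(self):
        spans = (EntitySpan(0, 5, "formula", "FML01"),)
        assert detect_joint_formula(spans, "FML01。") == []

    def test_joined_formula_requires_keyword(self):
        text = "FML01，JOIN FML02。"
        spans = (EntitySpan(0, 5, "formula", "FML01"),
                 EntitySpan(11, 16, "formula", "FML02"))
        jf, = detect_joint_formula(spans, text)
        assert [s.surface for g in jf.joined for s in g.spans] == ["FML02"]

    def test_removal_without_basic_formula_is_skipped(self, caplog):
        text = "REMOVE HRB01。"
        spans = (EntitySpan(7, 12, "herb", "HRB01"),)
        import logging
        with caplog.at_level(logging.WARNING):
            assert detect_joint_formula(spans, text) == []
        assert any("no preceding" in r.message for r in caplog.records)

    def test_dosage_token_captured(self):
        text = "FML01，ADD HRB013g。"
        spans = (EntitySpan(0, 5, "formula", "FML01"),
                 EntitySpan(10, 15, "herb", "HRB01"))
        jf, = detect_joint_formula(spans, text)
        assert jf.dosages[spans[1]] == "3g"

    def test_chinese_keywords(self):
        text = "甲方，加草药一三钱。"
        spans = (EntitySpan(0, 2, "formula", "甲方"),
                 EntitySpan(4, 7, "herb", "草药一"))
        jf, = detect_joint_formula(spans, text)
        assert [s.surface for g in jf.added for s in g.spans] == ["草药一"]
        assert jf.dosages[spans[1]] == "三钱"


class TestAttachBases:
    def _jf_with_add(self, text, spans, herb_idx):
        jf, = detect_joint_formula(spans, text)
        return jf

    def test_preceding_symptom_is_basis(self):
        text = "SYM01。FML01，ADD HRB01。"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(6, 11, "formula", "FML01"),
                 EntitySpan(16, 21, "herb", "HRB01"))
        jf, = detect_joint_formula(spans, text)
        attach_bases(jf, spans, [], Stage1Config())
        assert jf.added[0].basis == spans[0]

    def test_no_neighbor_within_window_leaves_basis_empty(self):
        text = "SYM01。" + "x" * 40 + "FML01，ADD HRB01。"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(46, 51, "formula", "FML01"),
                 EntitySpan(56, 61, "herb", "HRB01"))
        jf, = detect_joint_formula(spans, text)
        attach_bases(jf, spans, [], Stage1Config())
        assert jf.added[0].basis is None

    def test_nearer_following_side_wins(self):
        # symptom 7 chars before the group, disease 3 chars after it
        text = "SYM01，，，ADD HRB01，，，DIS01"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(12, 17, "herb", "HRB01"),
                 EntitySpan(20, 25, "disease", "DIS01"))
        jf = JointFormulaCombination(basic_formula=(spans[1],))
        from tcmkg.combinations import ModificationGroup
        jf.added.append(ModificationGroup(kind="add", spans=(spans[1],)))
        attach_bases(jf, spans, [], Stage1Config())
        # distances: preceding 12-5=7, following 20-17=3 -> following is nearer
        assert jf.added[0].basis == spans[2]

    def test_exact_tie_prefers_preceding(self):
        text = "SYM01，，ADD HRB01，，，，，，DIS01"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(11, 16, "herb", "HRB01"),
                 EntitySpan(22, 27, "disease", "DIS01"))
        jf = JointFormulaCombination(basic_formula=(spans[1],))
        from tcmkg.combinations import ModificationGroup
        grp = ModificationGroup(kind="add", spans=(spans[1],))
        jf.added.append(grp)
        attach_bases(jf, spans, [], Stage1Config())
        # both at distance 6 -> the preceding symptom wins
        assert grp.basis == spans[0]

    def test_combination_serves_as_atomic_basis(self):
        text = "SYM01，SYM02。FML01，ADD HRB01。"
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(6, 11, "symptom", "SYM02"),
                 EntitySpan(12, 17, "formula", "FML01"),
                 EntitySpan(22, 27, "herb", "HRB01"))
        combos = detect_same_type(spans, text)
        jf, = detect_joint_formula(spans, text)
        attach_bases(jf, spans, combos, Stage1Config())
        assert isinstance(jf.added[0].basis, SameTypeCombination)
        assert len(jf.added[0].basis.members) == 2


# ---------------------------------------------------------------------------
# differentiation-and-treatment combinations
# ---------------------------------------------------------------------------

def reference_dt(slot_sequence):
    """Independent re-implementation: greedy slot filling, emit on repeat."""
    out, cur = [], []
    for slot in slot_sequence:
        if slot in [s for s, in cur]:
            if len(cur) >= 2:
                out.append(len(cur))
            cur = []
        cur.append((slot,))
    if len(cur) >= 2:
        out.append(len(cur))
    return out


class TestDetectDT:
    def test_parallel_pairs_split_into_two(self, mk_article):
        a = mk_article([("pulse_condition", "PUL01"), ("cause_and_mechanism", "CAU01"),
                        ("pulse_condition", "PUL02"), ("cause_and_mechanism", "CAU02")])
        dts = detect_dt(a.spans)
        assert len(dts) == 2
        assert all(dt.n_filled == 2 for dt in dts)

    def test_single_element_never_emits(self, mk_article):
        a = mk_article([("disease", "DIS01")])
        assert detect_dt(a.spans) == []

    def test_full_process_fills_four_slots(self, mk_article):
        a = mk_article([("symptom", "SYM01"), ("symptom", "SYM02"),
                        ("cause_and_mechanism", "CAU01"),
                        ("therapeutic_principle_and_method", "TPM01"),
                        ("formula", "FML01")])
        combos = detect_same_type(a.spans, a.text)
        dts = detect_dt(a.spans, combos)
        assert len(dts) == 1
        assert dts[0].n_filled == 4
        assert isinstance(dts[0].slots["disease_or_sign"], SameTypeCombination)

    def test_no_span_in_two_combinations(self, mk_article):
        a = mk_article([("disease", "DIS01"), ("cause_and_mechanism", "CAU01"),
                        ("symptom", "SYM01"), ("cause_and_mechanism", "CAU02"),
                        ("formula", "FML01"), ("herb", "HRB01")])
        dts = detect_dt(a.spans)
        seen = set()
        for dt in dts:
            for sp in dt.member_spans():
                key = (sp.start, sp.end)
                assert key not in seen
                seen.add(key)

    def test_joint_formula_fills_remedy_slot_atomically(self):
        text = "CAU01。FML01，ADD HRB01。"
        spans = (EntitySpan(0, 5, "cause_and_mechanism", "CAU01"),
                 EntitySpan(6, 11, "formula", "FML01"),
                 EntitySpan(16, 21, "herb", "HRB01"))
        jfs = detect_joint_formula(spans, text)
        dts = detect_dt(spans, [], jfs)
        assert len(dts) == 1
        assert isinstance(dts[0].slots["formula_or_herb"], JointFormulaCombination)

    def test_emission_count_matches_reference_on_random_sequences(self):
        """Element-uniqueness closure equals an independent reference."""
        slot_of = {"disease": "ds", "symptom": "ds", "cause_and_mechanism": "cm",
                   "therapeutic_principle_and_method": "pm", "formula": "rx",
                   "herb": "rx"}
        rng = random.Random(20240901)
        for _ in range(200):
            n = rng.randint(1, 30)
            types = [rng.choice(list(slot_of)) for _ in range(n)]
            tokens = [(t, f"T{i:02d}") for i, t in enumerate(types)]
            a = make_article(tokens, sep="。")
            dts = detect_dt(a.spans)
            expected = reference_dt([slot_of[t] for t in types])
            assert [dt.n_filled for dt in dts] == expected
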