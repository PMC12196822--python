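"""Stage-2 triple instantiation under schema constraints."""

import itertools

import pytest

from tcmkg.combinations import (
    DTCombination,
    JointFormulaCombination,
    ModificationGroup,
    SameTypeCombination,
    detect_dt,
    detect_joint_formula,
    detect_same_type,
)
from tcmkg.corpus_io import EntitySpan
from tcmkg.instantiate import (
    NodeRegistry,
    attach_auxiliary,
    cooccurrence_edges,
    instantiate_dt,
    materialize_joint_formula,
)
from tcmkg.pipeline import extract_article
from tcmkg.schema import validate_triple_types


def spans_for(n, etype="symptom", prefix="SYM"):
    return tuple(
        EntitySpan(i * 6, i * 6 + 5, etype, f"{prefix}{i:02d}") for i in range(n)
    )


class TestCooccurrence:
    @pytest.mark.parametrize("n", range(2, 9))
    def test_count_is_pair_enumeration(self, schema, n):
        """C(n,2) edges, no duplicates, matching itertools pair order."""
        combo = SameTypeCombination("symptom_sign", spans_for(n))
        triples = cooccurrence_edges(combo, NodeRegistry(), schema)
        assert len(triples) == n * (n - 1) // 2
        assert len(set(triples)) == len(triples)
        expected_pairs = {
            (f"symptom:SYM{i:02d}", f"symptom:SYM{j:02d}")
            for i, j in itertools.combinations(range(n), 2)
        }
        assert {(t.subject, t.object) for t in triples} == expected_pairs
        assert all(t.relation == "co_occurrence" for t in triples)

    def test_repeated_mention_yields_no_self_loop(self, schema):
        spans = (EntitySpan(0, 5, "symptom", "SYM01"),
                 EntitySpan(6, 11, "symptom", "SYM01"))
        combo = SameTypeCombination("symptom_sign", spans)
        assert cooccurrence_edges(combo, NodeRegistry(), schema) == []


class TestMaterializeJointFormula:
    def test_basic_plus_dosed_addition_with_basis(self, schema):
        f = EntitySpan(6, 11, "formula", "FML01")
        h = EntitySpan(16, 21, "herb", "HRB01")
        sym = EntitySpan(0, 5, "symptom", "SYM01")
        jf = JointFormulaCombination(basic_formula=f)
        jf.added.append(ModificationGroup(kind="add", spans=(h,), basis=sym))
        jf.dosages[h] = "三钱"
        node, triples = materialize_joint_formula(jf, NodeRegistry(), schema, "A1", 1)
        assert node.node_id == "JF:A1:1" and node.is_virtual
        got = {(t.relation, t.object, t.attr_dict.get("dosage")) for t in triples}
        assert got == {
            ("basic_formula_is", "formula:FML01", None),
            ("add_herb_to_basic_formula", "herb:HRB01", "三钱"),
            ("basis_for_adding_herb", "symptom:SYM01", None),
        }

    def test_herb_group_basic_has_composition_edges_only(self, schema):
        herbs = spans_for(2, "herb", "HRB")
        jf = JointFormulaCombination(basic_formula=herbs)
        _, triples = materialize_joint_formula(jf, NodeRegistry(), schema, "A1", 1)
        assert {t.relation for t in triples} == {"composition_of_basic_formula_is"}
        assert len(triples) == 2

    def test_plain_formula_basic_single_edge(self, schema):
        jf = JointFormulaCombination(
            basic_formula=EntitySpan(0, 5, "formula", "FML01"))
        _, triples = materialize_joint_formula(jf, NodeRegistry(), schema, "A1", 1)
        assert [t.relation for t in triples] == ["basic_formula_is"]

    def test_combination_basis_expands_per_member(self, schema):
        f = EntitySpan(12, 17, "formula", "FML01")
        h = EntitySpan(22, 27, "herb", "HRB01")
        combo = SameTypeCombination("symptom_sign", spans_for(2))
        jf = JointFormulaCombination(basic_formula=f)
        jf.added.append(ModificationGroup(kind="add", spans=(h,), basis=combo))
        _, triples = materialize_joint_formula(jf, NodeRegistry(), schema, "A1", 1)
        bases = [t for t in triples if t.relation == "basis_for_adding_herb"]
        assert len(bases) == 2


def _dt_from_tokens(mk_article, tokens):
    a = mk_article(tokens)
    combos = detect_same_type(a.spans, a.text)
    return a, detect_dt(a.spans, combos)


class TestInstantiateDT:
    def test_worked_parallel_pulse_example(self, schema, mk_article):
        """Two parallel mechanism-pulse pairs give exactly two cause triples."""
        a = mk_article([
            ("pulse_condition", "soft pulse"),
            ("cause_and_mechanism", "Yin deficiency of viscera"),
            ("pulse_condition", "slippery pulse"),
            ("cause_and_mechanism", "phlegm heat"),
        ], sep="。")
        dts = detect_dt(a.spans)
        reg = NodeRegistry()
        triples = [t for dt in dts for t in instantiate_dt(dt, reg, schema)]
        assert {(t.subject, t.relation, t.object) for t in triples} == {
            ("cause_and_mechanism:Yin deficiency of viscera", "cause",
             "pulse_condition:soft pulse"),
            ("cause_and_mechanism:phlegm heat", "cause",
             "pulse_condition:slippery pulse"),
        }

    def test_combination_members_share_the_relation(self, schema, mk_article):
        a, dts = _dt_from_tokens(mk_article, [
            ("therapeutic_principle_and_method", "TPM01"),
            ("therapeutic_principle_and_method", "TPM02"),
            ("formula", "FML01"),
        ])
        assert len(dts) == 1
        triples = instantiate_dt(dts[0], NodeRegistry(), schema)
        uses = [t for t in triples if t.relation == "use"]
        assert len(uses) == 2

    def test_no_cross_combination_triples(self, schema, mk_article):
        a = mk_article([
            ("pulse_condition", "PUL01"), ("cause_and_mechanism", "CAU01"),
            ("pulse_condition", "PUL02"), ("cause_and_mechanism", "CAU02"),
        ], sep="。")
        dts = detect_dt(a.spans)
        reg = NodeRegistry()
        triples = [t for dt in dts for t in instantiate_dt(dt, reg, schema)]
        cross = {("cause_and_mechanism:CAU01", "cause", "pulse_condition:PUL02"),
                 ("cause_and_mechanism:CAU02", "cause", "pulse_condition:PUL01")}
        assert not cross & {(t.subject, t.relation, t.object) for t in triples}

    def test_virtual_node_stands_in_for_its_combination(self, schema):
        text = "CAU01。FML01，ADD HRB01。"
        spans = (EntitySpan(0, 5, "cause_and_mechanism", "CAU01"),
                 EntitySpan(6, 11, "formula", "FML01"),
                 EntitySpan(16, 21, "herb", "HRB01"))
        jfs = detect_joint_formula(spans, text)
        dts = detect_dt(spans, [], jfs)
        reg = NodeRegistry()
        vnode, _ = materialize_joint_formula(jfs[0], reg, schema, "A1", 1)
        triples = instantiate_dt(dts[0], reg, schema, jf_nodes={id(jfs[0]): vnode})
        assert {(t.subject, t.relation, t.object) for t in triples} == {
            ("JF:A1:1", "treat", "cause_and_mechanism:CAU01")}


class TestAttachAuxiliary:
    def test_time_links_to_adjacent_disease(self, schema, mk_article):
        a = mk_article([("time", "TIM01"), ("disease", "DIS01"),
                        ("cause_and_mechanism", "CAU01")])
        dts = detect_dt(a.spans)
        triples = attach_auxiliary(a.spans, dts, NodeRegistry(), schema)
        assert ("time:TIM01", "occurrence", "disease:DIS01") in {
            (t.subject, t.relation, t.object) for t in triples}

    def test_physician_links_to_all_combination_members(self, schema, mk_article):
        a = mk_article([
            ("symptom", "SYM01"), ("cause_and_mechanism", "CAU01"),
            ("therapeutic_principle_and_method", "TPM01"), ("formula", "FML01"),
            ("physician", "DOC01"),
        ], sep="。")
        dts = detect_dt(a.spans)
        triples = attach_auxiliary(a.spans, dts, NodeRegistry(), schema)
        discussed = {t.object for t in triples if t.subject == "physician:DOC01"}
        assert discussed == {"symptom:SYM01", "cause_and_mechanism:CAU01",
                             "therapeutic_principle_and_method:TPM01",
                             "formula:FML01"}

    def test_book_title_uses_reversed_direction(self, schema, mk_article):
        a = mk_article([("disease", "DIS01"), ("cause_and_mechanism", "CAU01"),
                        ("book_title", "BOK01")], sep="。")
        dts = detect_dt(a.spans)
        triples = attach_auxiliary(a.spans, dts, NodeRegistry(), schema)
        assert {(t.subject, t.relation, t.object) for t in triples} == {
            ("disease:DIS01", "record_in", "book_title:BOK01"),
            ("cause_and_mechanism:CAU01", "record_in", "book_title:BOK01"),
        }

    def test_auxiliary_without_dt_attaches_nothing(self, schema, mk_article):
        a = mk_article([("physician", "DOC01")])
        assert attach_auxiliary(a.spans, [], NodeRegistry(), schema) == []


class TestSchemaCompliance:
    def test_every_pipeline_triple_passes_validation(self, schema, mk_article):
        """All emitted triples satisfy the declared type patterns."""
        from tcmkg.fixtures import FixtureSpec, generate
        from tcmkg.pipeline import extract_corpus

        fc = generate(FixtureSpec(seed=11, n_articles=40))
        res = extract_corpus(fc.articles, schema)
        types = {nid: n.entity_type for nid, n in res.registry.nodes.items()}
        for t in res.triples:
            assert validate_triple_types(
                schema, types[t.subject], t.relation, types[t.object]), t

    def test_accounting_identity_of_relation_categories(self, schema):
        """total = co-occurrence + virtual + other, on every pipeline run."""
        from tcmkg.fixtures import FixtureSpec, generate
        from tcmkg.pipeline import extract_corpus

        fc = generate(FixtureSpec(seed=13, n_articles=40))
        res = extract_corpus(fc.articles, schema)
        n_cooc = sum(1 for t in res.triples if t.relation == "co_occurrence")
        n_virt = sum(1 for t in res.triples
                     if t.subject.startswith("JF:") or t.object.startswith("JF:"))
        n_other = sum(
            1 for t in res.triples
            if t.relation != "co_occurrence"
            and not (t.subject.startswith("JF:") or t.object.startswith("JF:")))
        assert n_cooc + n_virt + n_other == len(res.triples)
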