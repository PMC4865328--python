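import itertools

import pytest

from belpipe.bel_model import serialize_statement
from belpipe.grounding import GroundedEntity
from belpipe.recognition import Mention
from belpipe.relation_assembly import (
    RelationKeywordMap,
    adjust,
    assemble,
    count_adjustment_keywords,
    extract_statements,
    map_relation,
)
from belpipe.resources import DEFAULT_ADJUSTMENT_KEYWORDS, default_relation_map
from belpipe.srl_svo import SvoTuple


def entity(sentence, text, etype="protein", ns="HGNC", ident=None):
    start = sentence.index(text)
    m = Mention("s", start, start + len(text), text, etype)
    return GroundedEntity(m, ns, ident or text, 1, "exact")


class TestMapRelation:
    def test_stimulates_increases(self):
        assert map_relation("stimulate", default_relation_map()) == "increases"

    def test_reduced_decreases(self):
        assert map_relation("reduce", default_relation_map()) == "decreases"

    def test_unknown_verb_none(self):
        assert map_relation("discuss", default_relation_map()) is None

    def test_bad_relation_rejected(self):
        with pytest.raises(ValueError):
            RelationKeywordMap({"foo": "correlates"})


FIG2 = "Inhibition of COX2 markedly reduced both IL-1 beta and IL-6 release."


def fig2_svo():
    def span(phrase):
        start = FIG2.index(phrase)
        return (start, start + len(phrase))

    return SvoTuple(
        span("Inhibition of COX2"),
        "reduced",
        span("reduced"),
        span("both IL-1 beta and IL-6 release"),
    )


def fig2_entities():
    return [
        entity(FIG2, "COX2", ident="PTGS2"),
        entity(FIG2, "IL-1 beta", ident="IL1B"),
        entity(FIG2, "IL-6", ident="IL6"),
    ]


class TestAssemble:
    def test_fig2_pre_adjustment_pair(self):
        stmts = assemble(fig2_svo(), fig2_entities(), [], "decreases")
        assert [serialize_statement(s) for s in stmts] == [
            "p(HGNC:PTGS2) decreases p(HGNC:IL1B)",
            "p(HGNC:PTGS2) decreases p(HGNC:IL6)",
        ]

    def test_empty_subject_side(self):
        svo = fig2_svo()
        stmts = assemble(svo, fig2_entities()[1:], [], "decreases")
        assert stmts == []

    def test_cross_product_count(self):
        sent = "A and B reduced C and D."
        ents = [entity(sent, t) for t in "ABCD"]
        svo = SvoTuple((0, 7), "reduced", (8, 15), (16, 23))
        stmts = assemble(svo, ents, [], "decreases")
        assert len(stmts) == 4

    def test_unresolved_entities_skipped(self):
        sent = "A reduced B."
        good = entity(sent, "A")
        bad = GroundedEntity(Mention("s", 10, 11, "B", "protein"), "", "", 1, "unresolved")
        svo = SvoTuple((0, 1), "reduced", (2, 9), (10, 11))
        assert assemble(svo, [good, bad], [], "decreases") == []

    def test_duplicates_removed(self):
        sent = "A reduced A-ALIAS."
        a1 = entity(sent, "A")
        a2 = GroundedEntity(Mention("s", 10, 17, "A-ALIAS", "protein"), "HGNC", "A", 1, "exact")
        svo = SvoTuple((0, 1), "reduced", (2, 9), (10, 17))
        stmts = assemble(svo, [a1, a2], [], "decreases")
        assert len(stmts) == 1


class TestAdjust:
    def test_fig2_inhibition_flips(self):
        svo = fig2_svo()
        stmts = assemble(svo, fig2_entities(), [], "decreases")
        adjusted = adjust(stmts[0], svo, FIG2, DEFAULT_ADJUSTMENT_KEYWORDS)
        assert adjusted.relation == "increases"
        assert adjusted.provenance.adjusted

    def test_no_keyword_identity(self):
        sent = "COX2 reduced IL-6."
        ents = [entity(sent, "COX2", ident="PTGS2"), entity(sent, "IL-6", ident="IL6")]
        svo = SvoTuple((0, 4), "reduced", (5, 12), (13, 17))
        stmt = assemble(svo, ents, [], "decreases")[0]
        adjusted = adjust(stmt, svo, sent, DEFAULT_ADJUSTMENT_KEYWORDS)
        assert adjusted.relation == "decreases"
        assert not adjusted.provenance.adjusted

    def test_two_keywords_cancel(self):
        sent = "Inhibition of COX2 reduced inactivation of IL-6."
        ents = [entity(sent, "COX2", ident="PTGS2"), entity(sent, "IL-6", ident="IL6")]
        svo = SvoTuple((0, 18), "reduced", (19, 26), (27, len(sent) - 1))
        stmt = assemble(svo, ents, [], "decreases")[0]
        assert adjust(stmt, svo, sent, DEFAULT_ADJUSTMENT_KEYWORDS).relation == "decreases"

    def test_involution(self):
        svo = fig2_svo()
        stmt = assemble(svo, fig2_entities(), [], "decreases")[0]
        once = adjust(stmt, svo, FIG2, DEFAULT_ADJUSTMENT_KEYWORDS)
        twice = adjust(once, svo, FIG2, DEFAULT_ADJUSTMENT_KEYWORDS)
        assert twice.relation == stmt.relation

    @pytest.mark.parametrize("n_keywords", [0, 1, 2, 3])
    def test_parity_exhaustive(self, n_keywords):
        # place 0-3 flip keywords across subject/object phrases in every way
        keywords = ["inhibition", "mutant", "inactivation"][:n_keywords]
        for sides in itertools.product(["subj", "obj"], repeat=n_keywords):
            subj_words = ["AAA"] + [k for k, s in zip(keywords, sides) if s == "subj"]
            obj_words = ["BBB"] + [k for k, s in zip(keywords, sides) if s == "obj"]
            subj = " ".join(subj_words)
            obj = " ".join(obj_words)
            sent = f"{subj} reduced {obj}."
            ents = [entity(sent, "AAA"), entity(sent, "BBB")]
            svo = SvoTuple(
                (0, len(subj)),
                "reduced",
                (len(subj) + 1, len(subj) + 8),
                (len(subj) + 9, len(sent) - 1),
            )
            assert count_adjustment_keywords(svo, sent, DEFAULT_ADJUSTMENT_KEYWORDS) == n_keywords
            stmt = assemble(svo, ents, [], "decreases")[0]
            adjusted = adjust(stmt, svo, sent, DEFAULT_ADJUSTMENT_KEYWORDS)
            expected = "increases" if n_keywords % 2 == 1 else "decreases"
            assert adjusted.relation == expected


class TestExtractStatements:
    def test_fig2_end_to_end(self, bundle, resources, trees):
        sid, text = bundle.sentences[1]
        stmts = extract_statements(text, trees[1], resources, sentence_id=sid)
        assert {serialize_statement(s) for s in stmts} == {
            "p(HGNC:PTGS2) increases p(HGNC:IL1B)",
            "p(HGNC:PTGS2) increases p(HGNC:IL6)",
        }
        assert all(s.provenance.adjusted for s in stmts)

    def test_fig1_end_to_end(self, bundle, resources, trees):
        sid, text = bundle.sentences[0]
        stmts = extract_statements(text, trees[0], resources, sentence_id=sid)
        assert [serialize_statement(s) for s in stmts] == [
            "p(HGNC:MAP3K1) increases tscript(p(HGNC:AR))"
        ]

    def test_no_relation_verb_no_statements(self, bundle, resources, trees):
        sid, text = bundle.sentences[4]  # "... are essential to glycolysis."
        assert extract_statements(text, trees[4], resources, sentence_id=sid) == []

    def test_deterministic(self, bundle, resources, trees):
        for (sid, text), tree in zip(bundle.sentences, trees):
            a = extract_statements(text, tree, resources, sentence_id=sid)
            b = extract_statements(text, tree, resources, sentence_id=sid)
            assert [serialize_statement(s) for s in a] == [serialize_statement(s) for s in b]

    def test_subject_object_not_inverted(self, bundle, resources, trees):
        sid, text = bundle.sentences[2]
        stmts = extract_statements(text, trees[2], resources, sentence_id=sid)
        by_subject = {s.subject.value for s in stmts}
        assert by_subject == {"TNF", "IL5", "CSF2"}
        assert all(s.object.value == "BCL2" for s in stmts)
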