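import random

import pytest

from belpipe.srl_svo import (
    PAS,
    AlignmentError,
    PtbError,
    lemma_candidates,
    label_sentence,
    match_lemma,
    pas_to_svo,
    read_ptb,
    rule_srl,
)

SIMPLE = "(S (NP (NN A)) (VP (VBD reduced) (NP (NN B))))"


class TestReadPtb:
    def test_simple_three_leaf_tree(self):
        tree = read_ptb(SIMPLE, "A reduced B")
        leaves = tree.leaves()
        assert [l.token for l in leaves] == ["A", "reduced", "B"]
        assert [l.label for l in leaves] == ["NN", "VBD", "NN"]
        assert (leaves[1].start, leaves[1].end) == (2, 9)

    def test_fig3_tree_vp_contains_reduced(self, bundle):
        sid, text = bundle.sentences[1]
        tree = read_ptb(bundle.trees[1], text)
        verb = tree.find_leaf("reduced")
        assert verb is not None
        assert any(a.label == "VP" for a in verb.ancestors())

    def test_unbalanced_raises(self):
        with pytest.raises(PtbError):
            read_ptb("(S (NP A)", "A")

    def test_trailing_tokens_raise(self):
        with pytest.raises(PtbError):
            read_ptb("(S (NN A)) )", "A")

    def test_alignment_error_on_token_mismatch(self):
        with pytest.raises(AlignmentError):
            read_ptb(SIMPLE, "X unrelated Y")

    def test_node_span_is_union_of_children(self):
        tree = read_ptb(SIMPLE, "A reduced B")

        def check(node):
            if not node.is_leaf:
                assert node.start == min(c.start for c in node.children)
                assert node.end == max(c.end for c in node.children)
                for c in node.children:
                    check(c)

        check(tree.root)

    def test_root_wrapper_unwrapped(self):
        tree = read_ptb("(ROOT " + SIMPLE + ")", "A reduced B")
        assert tree.root.label == "S"

    def test_ptb_escapes(self):
        tree = read_ptb("(NP (NN X) (-LRB- -LRB-) (NN Y) (-RRB- -RRB-))", "X (Y)")
        assert [l.start for l in tree.leaves()] == [0, 2, 3, 4]


class TestRuleSrl:
    def test_simple_agent_and_patient(self):
        sent = "A reduced B"
        tree = read_ptb(SIMPLE, sent)
        pas = rule_srl(tree, tree.find_leaf("reduced"))
        assert pas.arg_text("ARG0", sent) == "A"
        assert pas.arg_text("ARG1", sent) == "B"

    def test_fig4_agent_recovered_above_grandparent(self, bundle):
        sid, text = bundle.sentences[2]
        tree = read_ptb(bundle.trees[2], text)
        pas = rule_srl(tree, tree.find_leaf("upregulated"))
        assert pas.arg_text("ARG0", text) == "IL-5 or GM-CSF"
        assert pas.arg_text("ARG1", text) == "BCL2 expression"

    def test_no_left_np_yields_arg1_only(self):
        sent = "Thus reduced B"
        tree = read_ptb("(S (ADVP (RB Thus)) (VP (VBD reduced) (NP (NN B))))", sent)
        pas = rule_srl(tree, tree.find_leaf("reduced"))
        assert "ARG0" not in pas.args
        assert pas.arg_text("ARG1", sent) == "B"

    def test_predicate_must_be_tree_leaf(self):
        tree = read_ptb(SIMPLE, "A reduced B")
        other = read_ptb(SIMPLE, "A reduced B")
        with pytest.raises(ValueError):
            rule_srl(tree, other.find_leaf("reduced"))

    def test_arg_spans_exclude_predicate(self):
        sent = "A reduced B"
        tree = read_ptb(SIMPLE, sent)
        pas = rule_srl(tree, tree.find_leaf("reduced"))
        for span in pas.args.values():
            assert span[1] <= pas.predicate_span[0] or span[0] >= pas.predicate_span[1]


def _oracle_agent(tree, verb_leaf):
    """Exhaustive search: walk S ancestors strictly above the parent, inner to
    outer; in each, the rightmost NP child wholly left of the verb."""
    ancestors = list(verb_leaf.ancestors())
    for anc in ancestors[1:]:
        if anc.label in ("S", "SINV", "SBAR"):
            nps = [c for c in anc.children if c.label == "NP" and c.end <= verb_leaf.start]
            if nps:
                return (nps[-1].start, nps[-1].end)
    return None


def _random_tree(rng, depth=0):
    if depth > 3 or rng.random() < 0.3:
        return f"({rng.choice(['NN', 'VBD', 'RB'])} w{rng.randint(0, 9)}{rng.randint(0, 9)})"
    label = rng.choice(["S", "NP", "VP", "ADVP", "SBAR"])
    children = " ".join(_random_tree(rng, depth + 1) for _ in range(rng.randint(1, 3)))
    return f"({label} {children})"


def test_rule_srl_agent_matches_oracle_on_random_trees():
    rng = random.Random(42)
    checked = 0
    for _ in range(300):
        ptb = f"(S {_random_tree(rng, 1)} {_random_tree(rng, 1)} {_random_tree(rng, 1)})"
        try:
            tmp = read_ptb(ptb, " ".join(t for t in ptb.replace("(", " ").replace(")", " ").split() if t.startswith("w")))
        except Exception:
            continue
        sent = tmp.sentence
        for leaf in tmp.leaves():
            if leaf.label != "VBD":
                continue
            pas = rule_srl(tmp, leaf)
            assert pas.args.get("ARG0") == _oracle_agent(tmp, leaf)
            checked += 1
    assert checked > 50


class TestPasToSvo:
    def test_fig2_mapping(self):
        sent = "Inhibition of COX2 markedly reduced both IL-1 beta and IL-6 release."
        def span(phrase):
            start = sent.index(phrase)
            return (start, start + len(phrase))

        pas = PAS(
            "reduced",
            span("reduced"),
            {
                "ARG0": span("Inhibition of COX2"),
                "ARG1": span("both IL-1 beta and IL-6 release"),
                "ARGM-MNR": span("markedly"),
            },
        )
        svo = pas_to_svo(pas)
        assert sent[svo.subject_span[0] : svo.subject_span[1]] == "Inhibition of COX2"
        assert svo.verb == "reduced"
        assert sent[svo.object_span[0] : svo.object_span[1]] == "both IL-1 beta and IL-6 release"

    def test_missing_patient_yields_none(self):
        assert pas_to_svo(PAS("reduced", (0, 7), {"ARG0": (8, 9)})) is None

    def test_argm_roles_ignored(self):
        base = PAS("reduced", (2, 9), {"ARG0": (0, 1), "ARG1": (10, 11)})
        extra = PAS("reduced", (2, 9), {"ARG0": (0, 1), "ARG1": (10, 11), "ARGM-TMP": (12, 20)})
        assert pas_to_svo(base) == pas_to_svo(extra)


class TestLemmas:
    @pytest.mark.parametrize(
        "word,lemma",
        [
            ("stimulates", "stimulate"),
            ("reduced", "reduce"),
            ("upregulated", "upregulate"),
            ("inhibited", "inhibit"),
            ("increases", "increase"),
            ("suppressed", "suppress"),
        ],
    )
    def test_relation_verb_lemmas(self, word, lemma, resources):
        assert match_lemma(word, resources.relation_map.lemmas) == lemma

    def test_non_relation_verb(self, resources):
        assert match_lemma("discusses", resources.relation_map.lemmas) is None

    def test_candidates_include_surface_form(self):
        assert "reduced" in lemma_candidates("Reduced")


class TestLabelSentence:
    def test_two_verbs_two_pas(self, bundle, resources):
        sid, text = bundle.sentences[2]
        tree = read_ptb(bundle.trees[2], text)
        pas = label_sentence(tree, resources.relation_map.lemmas)
        assert len(pas) == 2
        assert [p.predicate for p in pas] == ["downregulated", "upregulated"]

    def test_external_pas_passthrough(self):
        sent = "A reduced B"
        tree = read_ptb(SIMPLE, sent)
        ext = PAS("reduced", (2, 9), {"ARG0": (0, 1), "ARG1": (10, 11)})
        out = label_sentence(tree, {"reduce"}, [ext])
        assert out == [ext]

    def test_no_relation_verbs_no_pas(self):
        tree = read_ptb("(S (NP (NN A)) (VP (VBD discussed) (NP (NN B))))", "A discussed B")
        assert label_sentence(tree, {"reduce"}) == []

    def test_output_bounded_by_verbs_plus_external(self, bundle, resources):
        for (sid, text), ptb in zip(bundle.sentences, bundle.trees):
            tree = read_ptb(ptb, text)
            n_verbs = sum(1 for l in tree.leaves() if l.label.startswith("VB"))
            assert len(label_sentence(tree, resources.relation_map.lemmas)) <= n_verbs
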