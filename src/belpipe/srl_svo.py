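"""Constituency-parse ingestion and the rule-based syntactic labeler.

The labeler recovers an agent (ARG0) and a patient (ARG1) for a verb from
tree structure alone: the patient is the first NP/S/SBAR phrase following
the verb inside its verb phrase; the agent is the nearest NP among the
left-side children of the verb's nearest S ancestor at grandparent level or
above, climbing further up when a level has no left NP.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

PTB_UNESCAPE = {
    "-LRB-": "(",
    "-RRB-": ")",
    "-LSB-": "[",
    "-RSB-": "]",
    "-LCB-": "{",
    "-RCB-": "}",
    "``": '"',
    "''": '"',
}


class PtbError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(eq=False)
class TreeNode:
    label: str
    children: List["TreeNode"] = field(default_factory=list)
    token: Optional[str] = None  # set on leaves only
    start: int = -1  # character offsets into the sentence
    end: int = -1
    parent: Optional["TreeNode"] = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.token is not None

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: List[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def span_text(self, sentence: str) -> str:
        return sentence[self.start : self.end]

    def ancestors(self) -> Iterator["TreeNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent


@dataclass
class ParseTree:
    root: TreeNode
    sentence: str

    def leaves(self) -> List[TreeNode]:
        return self.root.leaves()

    def find_leaf(self, token: str, occurrence: int = 0) -> Optional[TreeNode]:
        hits = [l for l in self.leaves() if l.token == token]
        return hits[occurrence] if occurrence < len(hits) else None


def _tokenize_ptb(text: str) -> List[str]:
    return re.findall(r"\(|\)|[^\s()]+", text)


def _parse_node(tokens: List[str], pos: int) -> Tuple[TreeNode, int]:
    if tokens[pos] != "(":
        raise PtbError(f"expected '(' at token {pos}")
    pos += 1
    if pos >= len(tokens) or tokens[pos] in "()":
        raise PtbError(f"expected node label at token {pos}")
    node = TreeNode(label=tokens[pos])
    pos += 1
    while pos < len(tokens) and tokens[pos] != ")":
        if tokens[pos] == "(":
            child, pos = _parse_node(tokens, pos)
            child.parent = node
            node.children.append(child)
        else:
            leaf = TreeNode(label=node.label, token=tokens[pos], parent=node)
            node.children.append(leaf)
            pos += 1
    if pos >= len(tokens):
        raise PtbError("unbalanced brackets: unexpected end of input")
    # collapse a preterminal (POS tag over a single raw token) into one leaf;
    # the raw-token child inherited this node's label, which distinguishes it
    # from an already-collapsed single-child phrase like (NP (NN A))
    if (
        len(node.children) == 1
        and node.children[0].is_leaf
        and node.children[0].label == node.label
    ):
        node.token = node.children[0].token
        node.children = []
    return node, pos + 1


def _align(root: TreeNode, sentence: str) -> None:
    cursor = 0
    for idx, leaf in enumerate(root.leaves()):
        surface = PTB_UNESCAPE.get(leaf.token, leaf.token)
        found = sentence.find(surface, cursor)
        if found < 0:
            raise AlignmentError(
                f"token {idx} ({leaf.token!r}) not found in sentence after offset {cursor}"
            )
        leaf.start, leaf.end = found, found + len(surface)
        cursor = leaf.end

    def set_spans(node: TreeNode) -> Tuple[int, int]:
        if node.is_leaf:
            return node.start, node.end
        spans = [set_spans(c) for c in node.children]
        node.start = min(s for s, _ in spans)
        node.end = max(e for _, e in spans)
        return node.start, node.end

    set_spans(root)


def read_ptb(text: str, sentence: str) -> ParseTree:
    """Parse one bracketed Penn-Treebank tree and align leaves to the sentence."""
    tokens = _tokenize_ptb(text.strip())
    if not tokens:
        raise PtbError("empty tree")
    root, pos = _parse_node(tokens, 0)
    if pos != len(tokens):
        raise PtbError(f"unbalanced brackets: trailing tokens at {pos}")
    # unwrap a bare ROOT/TOP wrapper
    if root.label in ("ROOT", "TOP") and len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
    _align(root, sentence)
    return ParseTree(root, sentence)


def read_ptb_file(path: str | Path, sentences: Sequence[str]) -> List[ParseTree]:
    """One tree per non-empty line, aligned to ``sentences`` by record order."""
    lines = [l for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()]
    if len(lines) != len(sentences):
        raise AlignmentError(f"{len(lines)} trees for {len(sentences)} sentences")
    return [read_ptb(line, sent) for line, sent in zip(lines, sentences)]


@dataclass(frozen=True)
class PAS:
    """A predicate with role-labeled argument spans (character offsets)."""

    predicate: str
    predicate_span: Tuple[int, int]
    args: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def arg_text(self, role: str, sentence: str) -> Optional[str]:
        span = self.args.get(role)
        return sentence[span[0] : span[1]] if span else None


@dataclass(frozen=True)
class SvoTuple:
    subject_span: Tuple[int, int]
    verb: str
    verb_span: Tuple[int, int]
    object_span: Tuple[int, int]


_PHRASE_ARG_LABELS = {"NP", "S", "SBAR"}


def _first_patient_after(verb_leaf: TreeNode) -> Optional[TreeNode]:
    """First NP/S/SBAR sibling following the verb within its verb phrase."""
    node = verb_leaf
    for parent in verb_leaf.ancestors():
        idx = parent.children.index(node)
        for sib in parent.children[idx + 1 :]:
            if sib.label in _PHRASE_ARG_LABELS:
                return sib
        if not parent.label.startswith("VP"):
            break
        node = parent
    return None


def _nearest_left_np(s_node: TreeNode, verb_leaf: TreeNode) -> Optional[TreeNode]:
    cands = [
        c for c in s_node.children if c.label == "NP" and c.end <= verb_leaf.start
    ]
    return cands[-1] if cands else None


def rule_srl(tree: ParseTree, verb_leaf: TreeNode) -> PAS:
    """Recover agent/patient for a verb leaf from tree structure."""
    if verb_leaf.token is None or verb_leaf not in tree.leaves():
        raise ValueError("predicate must be a leaf of the tree")
    args: Dict[str, Tuple[int, int]] = {}

    patient = _first_patient_after(verb_leaf)
    if patient is not None:
        args["ARG1"] = (patient.start, patient.end)

    # agent: nearest S ancestor at grandparent level or above with a left NP
    ancestors = list(verb_leaf.ancestors())
    for anc in ancestors[1:]:  # skip the immediate parent
        if anc.label in ("S", "SINV", "SBAR"):
            agent = _nearest_left_np(anc, verb_leaf)
            if agent is not None:
                args["ARG0"] = (agent.start, agent.end)
                break
    return PAS(verb_leaf.token, (verb_leaf.start, verb_leaf.end), args)


def pas_to_svo(pas: PAS) -> Optional[SvoTuple]:
    """Map predicate/agent/patient onto verb/subject/object; ARGM-* roles ignored."""
    if "ARG0" not in pas.args or "ARG1" not in pas.args:
        return None
    return SvoTuple(pas.args["ARG0"], pas.predicate, pas.predicate_span, pas.args["ARG1"])


_SUFFIX_RULES: Tuple[Tuple[str, str], ...] = (
    ("ies", "y"),
    ("es", ""),
    ("s", ""),
    ("d", ""),
    ("ed", ""),
    ("ing", "e"),
    ("ing", ""),
)


def lemma_candidates(word: str) -> List[str]:
    """Surface form plus suffix-stripped candidates (no external resources)."""
    w = word.lower()
    out = [w]
    for suffix, repl in _SUFFIX_RULES:
        if w.endswith(suffix) and len(w) > len(suffix) + 1:
            cand = w[: -len(suffix)] + repl
            if cand not in out:
                out.append(cand)
    return out


def match_lemma(word: str, lemmas: Set[str]) -> Optional[str]:
    for cand in lemma_candidates(word):
        if cand in lemmas:
            return cand
    return None


def _verb_leaves(tree: ParseTree) -> List[TreeNode]:
    return [l for l in tree.leaves() if l.label.startswith("VB")]


def load_external_pas(path: str | Path) -> Dict[str, List[PAS]]:
    """JSON Lines: ``sentence_id, predicate, predicate_span, roles{ROLE: [start, end]}``."""
    out: Dict[str, List[PAS]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip():
                continue
            rec = json.loads(raw)
            pas = PAS(
                rec["predicate"],
                tuple(rec["predicate_span"]),
                {role: tuple(span) for role, span in rec.get("roles", {}).items()},
            )
            out.setdefault(str(rec["sentence_id"]), []).append(pas)
    return out


def label_sentence(
    tree: ParseTree,
    relation_verbs: Set[str],
    external_pas: Optional[Sequence[PAS]] = None,
) -> List[PAS]:
    """One PAS per relation-verb occurrence; external records take precedence.

    External PAS (standing in for a statistical labeler) are used for their
    predicate occurrences; the rule-based labeler fills in every relation-verb
    leaf not covered by an external record.
    """
    external_pas = list(external_pas or [])
    covered = {p.predicate_span for p in external_pas}
    out: List[PAS] = list(external_pas)
    for leaf in _verb_leaves(tree):
        if match_lemma(leaf.token, relation_verbs) is None:
            continue
        if (leaf.start, leaf.end) in covered:
            continue
        out.append(rule_srl(tree, leaf))
    return sorted(out, key=lambda p: p.predicate_span)
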