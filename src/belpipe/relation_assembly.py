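"""SVO-to-statement assembly and keyword polarity adjustment.

Relation verbs map to ``increases``/``decreases`` via a lemma table (the
regulation/positive-regulation event families map to increases and the
negative-regulation family to decreases).  Entities inside the subject phrase
become BEL subjects, entities inside the object phrase become objects, and
the cross product is emitted.  Adjustment keywords such as "inhibition"
occurring in the subject or object phrase flip the relation; with several
keywords the flip is applied once per keyword (parity rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from belpipe.bel_model import ABUNDANCE_HEADS, BelStatement, BelTerm, Provenance, canonicalize
from belpipe.function_classification import FunctionAssignment, FunctionPattern, classify_functions
from belpipe.grounding import GroundedEntity, ground_all
from belpipe.lexicon import Lexicon
from belpipe.recognition import DEFAULT_PRECEDENCE, Mention, max_match, merge_mentions, tokenize
from belpipe.srl_svo import PAS, ParseTree, SvoTuple, label_sentence, match_lemma, pas_to_svo

logger = logging.getLogger(__name__)

RELATION_TYPES = ("increases", "decreases")

_TYPE_TO_KIND = {
    "protein": "protein",
    "chemical": "chemical",
    "bioprocess": "bioprocess",
    "disease": "pathology",
}


class RelationKeywordMap:
    """Verb lemma -> relation type."""

    def __init__(self, mapping: Dict[str, str]):
        for lemma, rel in mapping.items():
            if rel not in RELATION_TYPES:
                raise ValueError(f"lemma {lemma!r} maps to unknown relation {rel!r}")
        self.mapping = dict(mapping)

    @property
    def lemmas(self) -> Set[str]:
        return set(self.mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "RelationKeywordMap":
        mapping: Dict[str, str] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}: line {lineno}: expected lemma<TAB>relation")
                mapping[parts[0].strip().lower()] = parts[1].strip()
        return cls(mapping)


def load_adjustment_keywords(path: str | Path) -> FrozenSet[str]:
    """One lowercase keyword per line."""
    words = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def map_relation(verb_lemma: str, kmap: RelationKeywordMap) -> Optional[str]:
    """Relation type for a verb lemma, or None for non-relation verbs."""
    return kmap.mapping.get(verb_lemma.lower())


def _term_for(entity: GroundedEntity, wrap: Optional[FunctionAssignment]) -> BelTerm:
    kind = _TYPE_TO_KIND[entity.mention.entity_type]
    base = BelTerm(kind, entity.namespace, entity.identifier)
    if wrap is None:
        return base
    if wrap.function == "complex":
        members = tuple(
            BelTerm(_TYPE_TO_KIND[e.mention.entity_type], e.namespace, e.identifier)
            for e in wrap.entities
        )
        return replace(members[0], function_wrap="complex", wrap_members=members)
    return replace(base, function_wrap=wrap.function,
                   pmod_type=wrap.pmod_type if wrap.function == "pmod" else None)


def _inside(span: Tuple[int, int], mention: Mention) -> bool:
    return span[0] <= mention.start and mention.end <= span[1]


def _side_terms(
    span: Tuple[int, int],
    entities: Sequence[GroundedEntity],
    wraps: Sequence[FunctionAssignment],
) -> List[BelTerm]:
    """BEL terms for the resolved entities inside one SVO side.

    A complex wrap whose members all fall inside the span contributes a single
    complex term in place of its members.
    """
    wrap_of = {}
    for w in wraps:
        for e in w.entities:
            wrap_of[id(e)] = w
    inside = [e for e in entities if e.resolved and _inside(span, e.mention)]
    terms: List[BelTerm] = []
    emitted_complexes: Set[int] = set()
    for e in inside:
        w = wrap_of.get(id(e))
        if w is not None and w.function == "complex":
            if id(w) in emitted_complexes:
                continue
            if all(_inside(span, m.mention) for m in w.entities):
                terms.append(_term_for(e, w))
                emitted_complexes.add(id(w))
            else:
                terms.append(_term_for(e, None))
        else:
            terms.append(_term_for(e, w))
    return terms


def assemble(
    svo: SvoTuple,
    entities: Sequence[GroundedEntity],
    wraps: Sequence[FunctionAssignment],
    relation: str,
    sentence_id: Optional[str] = None,
) -> List[BelStatement]:
    """Cross product of subject-side and object-side terms; duplicates removed."""
    if relation not in RELATION_TYPES:
        raise ValueError(f"unknown relation {relation!r}")
    subjects = _side_terms(svo.subject_span, entities, wraps)
    objects = _side_terms(svo.object_span, entities, wraps)
    out: List[BelStatement] = []
    seen: Set[str] = set()
    prov = Provenance(sentence_id=sentence_id)
    for s in subjects:
        for o in objects:
            stmt = BelStatement(s, relation, o, provenance=prov)
            key = canonicalize(stmt)
            if key not in seen:
                seen.add(key)
                out.append(stmt)
    return out


def count_adjustment_keywords(
    svo: SvoTuple, sentence: str, adjustment: FrozenSet[str]
) -> int:
    count = 0
    for span in (svo.subject_span, svo.object_span):
        for tok in tokenize(sentence[span[0] : span[1]]):
            if tok.text.lower() in adjustment:
                count += 1
    return count


def adjust(
    statement: BelStatement,
    svo: SvoTuple,
    sentence: str,
    adjustment: FrozenSet[str],
) -> BelStatement:
    """Flip the relation when an odd number of adjustment keywords occurs
    in the subject or object phrase; even counts leave it unchanged."""
    if count_adjustment_keywords(svo, sentence, adjustment) % 2 == 1:
        return statement.flipped()
    return statement


@dataclass
class PipelineResources:
    """Everything :func:`extract_statements` needs besides the sentence/tree."""

    lexicons: Dict[str, Lexicon]
    patterns: Sequence[FunctionPattern]
    relation_map: RelationKeywordMap
    adjustment: FrozenSet[str]
    precedence: Sequence[str] = DEFAULT_PRECEDENCE


def extract_statements(
    sentence: str,
    tree: ParseTree,
    resources: PipelineResources,
    sentence_id: str = "",
    plugin_mentions: Sequence[Mention] = (),
    external_pas: Sequence[PAS] = (),
) -> List[BelStatement]:
    """Full pipeline: recognize, ground, classify functions, label roles, assemble."""
    per_recognizer = [
        max_match(sentence, lex, sentence_id) for lex in resources.lexicons.values()
    ]
    if plugin_mentions:
        per_recognizer.append(list(plugin_mentions))
    mentions = merge_mentions(per_recognizer, resources.precedence) if per_recognizer else []
    entities = ground_all(mentions, resources.lexicons)
    wraps = classify_functions(sentence, entities, resources.patterns)
    pas_list = label_sentence(tree, resources.relation_map.lemmas, external_pas)

    statements: List[BelStatement] = []
    seen: Set[str] = set()
    for pas in pas_list:
        svo = pas_to_svo(pas)
        if svo is None:
            continue
        lemma = match_lemma(svo.verb, resources.relation_map.lemmas)
        relation = map_relation(lemma, resources.relation_map) if lemma else None
        if relation is None:
            continue
        for stmt in assemble(svo, entities, wraps, relation, sentence_id):
            adjusted = adjust(stmt, svo, sentence, resources.adjustment)
            key = canonicalize(adjusted)
            if key not in seen:
                seen.add(key)
                statements.append(adjusted)
    logger.debug(
        "%s: %d mentions, %d grounded, %d wraps, %d PAS, %d statements",
        sentence_id,
        len(mentions),
        sum(1 for e in entities if e.resolved),
        len(wraps),
        len(pas_list),
        len(statements),
    )
    return statements
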