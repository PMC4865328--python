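"""Scoring of predicted against gold statements at four granularities.

Level projections of a statement:

- ``term``      — the (namespace, identifier) of every abundance it mentions
                  (complex members contribute individually);
- ``function``  — (identifier, wrap) for wrapped terms only;
- ``relation``  — (subject identifier, relation, object identifier);
- ``bel``       — the full canonical statement string.

Matching is per-sentence bag (multiset) matching: each gold item can satisfy
at most one predicted item.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Optional, Sequence, Tuple

from belpipe.bel_model import BelStatement, BelTerm, canonicalize, serialize_term
from belpipe.lexicon import Lexicon, expand_variants
from belpipe.recognition import Mention, max_match, tokenize

LEVELS = ("term", "function", "relation", "bel")


@dataclass(frozen=True)
class EvalReport:
    level: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "level": self.level,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _base_terms(term: BelTerm) -> List[BelTerm]:
    if term.function_wrap == "complex":
        return list(term.wrap_members)
    return [term]


def _project(statement: BelStatement, level: str) -> List[Hashable]:
    if level == "term":
        return [
            (t.namespace, t.value)
            for side in (statement.subject, statement.object)
            for t in _base_terms(side)
        ]
    if level == "function":
        out = []
        for side in (statement.subject, statement.object):
            if side.function_wrap is not None:
                wrap = side.function_wrap
                if wrap == "complex":
                    ids = tuple(sorted((m.namespace, m.value) for m in side.wrap_members))
                    out.append((ids, wrap))
                else:
                    out.append(((side.namespace, side.value), wrap))
        return out
    if level == "relation":
        return [
            (
                (statement.subject.namespace, statement.subject.value),
                statement.relation,
                (statement.object.namespace, statement.object.value),
            )
        ]
    if level == "bel":
        return [canonicalize(statement)]
    raise ValueError(f"unknown level {level!r}")


def score(
    gold: Dict[str, Sequence[BelStatement]],
    pred: Dict[str, Sequence[BelStatement]],
    level: str,
) -> EvalReport:
    """Per-sentence bag matching of level projections."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    tp = fp = fn = 0
    for sid in set(gold) | set(pred):
        gold_bag: Counter = Counter()
        for s in gold.get(sid, ()):
            gold_bag.update(_project(s, level))
        pred_bag: Counter = Counter()
        for s in pred.get(sid, ()):
            pred_bag.update(_project(s, level))
        common = sum((gold_bag & pred_bag).values())
        tp += common
        fp += sum(pred_bag.values()) - common
        fn += sum(gold_bag.values()) - common
    return EvalReport(level, tp, fp, fn)


def score_all(
    gold: Dict[str, Sequence[BelStatement]],
    pred: Dict[str, Sequence[BelStatement]],
) -> Dict[str, EvalReport]:
    return {level: score(gold, pred, level) for level in LEVELS}


@dataclass(frozen=True)
class SpanRecovery:
    identifier: str
    mention: Optional[Mention]
    method: str  # synonym | nearest_id | unmapped


def _find_synonym_span(
    identifier_names: Iterable[str], sentence: str, lexicon: Lexicon, sentence_id: str
) -> Optional[Mention]:
    tokens = tokenize(sentence)
    targets = set()
    for name in identifier_names:
        targets |= expand_variants(name, lexicon.general_words, lexicon.stop_words)
    best: Optional[Tuple[int, int]] = None
    for i in range(len(tokens)):
        if tokens[i].text.lower() in lexicon.stop_words:
            continue
        for j in range(min(len(tokens), i + 8) - 1, i - 1, -1):
            text = sentence[tokens[i].start : tokens[j].end]
            if expand_variants(text, lexicon.general_words, lexicon.stop_words) & targets:
                if best is None or (tokens[j].end - tokens[i].start) > (best[1] - best[0]):
                    best = (tokens[i].start, tokens[j].end)
                break
    if best is None:
        return None
    return Mention(sentence_id, best[0], best[1], sentence[best[0] : best[1]],
                   lexicon.entity_type)


def recover_gold_spans(
    gold_identifiers: Sequence[Tuple[str, str]],
    sentence: str,
    lexicon: Lexicon,
    sentence_id: str = "",
) -> List[SpanRecovery]:
    """Map gold (namespace, identifier) pairs back to sentence spans.

    Each identifier's dictionary names are searched in the sentence (variant
    expanded).  A numeric gene identifier that cannot be mapped falls back to
    the recognized mention whose candidate identifier has the smallest
    absolute numeric distance to the gold identifier.
    """
    recognized = max_match(sentence, lexicon, sentence_id)
    out: List[SpanRecovery] = []
    for namespace, identifier in gold_identifiers:
        entry = lexicon.entry_for(namespace, identifier)
        names = list(entry.names) if entry else [identifier]
        hit = _find_synonym_span(names, sentence, lexicon, sentence_id)
        if hit is not None:
            out.append(SpanRecovery(identifier, hit, "synonym"))
            continue
        if identifier.isdigit():
            best: Optional[Tuple[int, Mention]] = None
            for m in recognized:
                for ns, cand in sorted(lexicon.lookup_text(m.text)):
                    if not cand.isdigit():
                        continue
                    dist = abs(int(cand) - int(identifier))
                    if best is None or dist < best[0]:
                        best = (dist, m)
            if best is not None:
                out.append(SpanRecovery(identifier, best[1], "nearest_id"))
                continue
        out.append(SpanRecovery(identifier, None, "unmapped"))
    return out


def format_report(reports: Dict[str, EvalReport]) -> str:
    lines = ["level\ttp\tfp\tfn\tprecision\trecall\tf1"]
    for level in LEVELS:
        if level not in reports:
            continue
        r = reports[level]
        lines.append(
            f"{r.level}\t{r.tp}\t{r.fp}\t{r.fn}\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}"
        )
    return "\n".join(lines)
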