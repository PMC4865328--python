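"""Dictionary recognizers: greedy leftmost-longest matching over token n-grams.

Tokenization splits on whitespace and punctuation but keeps hyphens, internal
periods and apostrophes inside tokens (``IL-1`` is one token); a slash is its
own token so patterns like ``A / B complex`` can address it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import re
from typing import Iterable, List, Optional, Sequence, Tuple

from belpipe.lexicon import ENTITY_TYPES, Lexicon

logger = logging.getLogger(__name__)

DEFAULT_PRECEDENCE = ("protein", "chemical", "disease", "bioprocess")

_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9\-._']*[A-Za-z0-9])?|/")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(sentence: str) -> List[Token]:
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence)]


@dataclass(frozen=True)
class Mention:
    """A typed character span; offsets are 0-based half-open into the sentence."""

    sentence_id: str
    start: int
    end: int
    text: str
    entity_type: str
    source: str = "dictionary"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")

    def validate_against(self, sentence: str) -> None:
        if self.end > len(sentence):
            raise ValueError(f"span end {self.end} beyond sentence length {len(sentence)}")
        if sentence[self.start : self.end] != self.text:
            raise ValueError(
                f"text {self.text!r} != sentence slice {sentence[self.start:self.end]!r}"
            )

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


_MAX_NGRAM = 8


def max_match(sentence: str, lexicon: Lexicon, sentence_id: str = "") -> List[Mention]:
    """Greedy left-to-right longest dictionary match over token n-grams.

    At each token position the longest n-gram whose variant-expanded key hits
    the lexicon index is emitted and its tokens consumed, so one recognizer
    never produces overlapping mentions.
    """
    tokens = tokenize(sentence)
    if not lexicon.index:
        return []
    cap = min(_MAX_NGRAM, max(lexicon.max_key_tokens + 2, 1))
    mentions: List[Mention] = []
    i = 0
    while i < len(tokens):
        # a mention never starts on an article/preposition
        if tokens[i].text.lower() in lexicon.stop_words:
            i += 1
            continue
        matched = False
        for j in range(min(len(tokens), i + cap) - 1, i - 1, -1):
            span_text = sentence[tokens[i].start : tokens[j].end]
            if lexicon.lookup_text(span_text):
                mentions.append(
                    Mention(sentence_id, tokens[i].start, tokens[j].end, span_text,
                            lexicon.entity_type, source="dictionary")
                )
                i = j + 1
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def merge_mentions(
    per_recognizer: Sequence[Sequence[Mention]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> List[Mention]:
    """Resolve overlaps across recognizers: longer span wins, ties by type precedence.

    All mentions must reference the same sentence id; the result is
    non-overlapping and sorted by start offset.
    """
    flat = [m for group in per_recognizer for m in group]
    if not flat:
        return []
    ids = {m.sentence_id for m in flat}
    if len(ids) > 1:
        raise ValueError(f"mentions from different sentences: {sorted(ids)}")
    prec = {t: i for i, t in enumerate(precedence)}
    ranked = sorted(
        flat, key=lambda m: (-m.length, prec.get(m.entity_type, len(prec)), m.start, m.source)
    )
    kept: List[Mention] = []
    for m in ranked:
        if not any(m.overlaps(k) for k in kept):
            kept.append(m)
    # identical spans of the same rank collapse via exact-duplicate removal
    return sorted(set(kept), key=lambda m: (m.start, m.end))


def run_plugin(sentence: str, plugin_path: str | Path, sentence_id: str = "") -> List[Mention]:
    """Read externally produced mentions (JSON Lines) for one sentence.

    Records whose offsets do not fit the sentence are skipped with a warning;
    fields: ``sentence_id, start, end, type, score``.
    """
    mentions: List[Mention] = []
    skipped = 0
    with Path(plugin_path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            rec = json.loads(raw)
            if sentence_id and rec.get("sentence_id") not in (None, sentence_id):
                continue
            try:
                m = Mention(
                    sentence_id or str(rec.get("sentence_id", "")),
                    int(rec["start"]),
                    int(rec["end"]),
                    sentence[int(rec["start"]) : int(rec["end"])],
                    rec["type"],
                    source="plugin",
                )
                m.validate_against(sentence)
            except (KeyError, ValueError) as exc:
                skipped += 1
                logger.warning("%s: line %d: skipped plugin record (%s)", plugin_path, lineno, exc)
                continue
            mentions.append(m)
    if skipped:
        logger.info("%s: %d plugin records skipped", plugin_path, skipped)
    return sorted(mentions, key=lambda m: (m.start, m.end))
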