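"""Dictionary loading and the heuristic surface-normalization rule engine.

Normalization has two layers: a deterministic *basic* pass
(:func:`normalize_surface`) applied to every key and query, and optional
*variant* rule families (:func:`expand_variants`) whose closure expands both
dictionary keys and mention text — parenthesis rewriting, space removal,
general-word removal, and stop-word removal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("protein", "chemical", "bioprocess", "disease")

# Removable general words; seeded with the printed examples only, editable config.
DEFAULT_GENERAL_WORDS = frozenset({"group", "residue", "protein", "atom"})
# Articles and common prepositions.
DEFAULT_STOP_WORDS = frozenset(
    {"a", "an", "the", "of", "in", "on", "at", "by", "for", "to", "with"}
)


class DictionaryFormatError(ValueError):
    """Malformed dictionary file; message names the offending line."""


@dataclass(frozen=True)
class DictionaryEntry:
    namespace: str
    identifier: str
    preferred_name: str
    synonyms: Tuple[str, ...]
    entity_type: str

    @property
    def names(self) -> Tuple[str, ...]:
        return (self.preferred_name,) + self.synonyms


def _strip_h_prefix(original: str) -> bool:
    """True when a leading 'h' looks like a species prefix, e.g. 'hTERT'."""
    return re.match(r"^h[A-Z][A-Za-z0-9]*$", original) is not None


def normalize_surface(text: str) -> str:
    """Apply the basic normalization rules; total and idempotent.

    Lowercase; remove hyphens and periods; strip leading "human " (repeatedly)
    and a leading species "h" prefix (judged on the original casing); strip one
    trailing "s" unless preceded by another "s" or the string is very short;
    collapse whitespace.
    """
    strip_h = _strip_h_prefix(text.strip())
    s = text.lower()
    s = s.replace("-", "").replace(".", "")
    s = re.sub(r"\s+", " ", s).strip()
    while s.startswith("human "):
        s = s[len("human ") :]
    if strip_h:
        s = s[1:]
    # iterate: stripping may expose another trailing "s" across whitespace
    while len(s) > 2 and s.endswith("s") and not s.endswith("ss"):
        s = s[:-1].rstrip()
    return s.strip()


_PAREN_RE = re.compile(r"\(([^()]*)\)")


def _paren_variants(s: str) -> Set[str]:
    """'AAA(A)' -> {'AAA-A', 'AAAA'}; drops the parentheses either way."""
    if "(" not in s:
        return set()
    hyphenated = _PAREN_RE.sub(lambda m: "-" + m.group(1), s)
    fused = _PAREN_RE.sub(lambda m: m.group(1), s)
    return {hyphenated, fused}


def _remove_space(s: str) -> Set[str]:
    return {s.replace(" ", "")} if " " in s else set()


def _remove_words(s: str, words: FrozenSet[str]) -> Set[str]:
    tokens = s.split(" ")
    kept = [t for t in tokens if t not in words]
    if len(kept) == len(tokens) or not kept:
        return set()
    return {" ".join(kept)}


def expand_variants(
    text: str,
    general_words: FrozenSet[str] = DEFAULT_GENERAL_WORDS,
    stop_words: FrozenSet[str] = DEFAULT_STOP_WORDS,
) -> Set[str]:
    """Closure of the optional rule families over :func:`normalize_surface`.

    Always contains ``normalize_surface(text)``.  Parenthesis rewrites are
    emitted both hyphenated and fused (the hyphen would be removed again by
    the basic pass, so both forms are useful as index keys).
    """
    base = normalize_surface(text)
    seen: Set[str] = {base}
    # Parenthesis rules act on the raw (lowercased) string since the basic
    # pass does not touch parentheses.
    frontier = {base}
    for _ in range(4):  # each family applies at most once per chain
        new: Set[str] = set()
        for s in frontier:
            for candidate in (
                _paren_variants(s)
                | _remove_space(s)
                | _remove_words(s, general_words)
                | _remove_words(s, stop_words)
            ):
                candidate = re.sub(r"\s+", " ", candidate).strip()
                if candidate and candidate not in seen:
                    new.add(candidate)
        if not new:
            break
        seen |= new
        frontier = new
    # re-normalized forms of every variant are valid keys too
    seen |= {normalize_surface(v) for v in set(seen)}
    seen.discard("")
    return seen


@dataclass
class Lexicon:
    """A typed dictionary with a variant-expanded lookup index."""

    entity_type: str
    entries: List[DictionaryEntry] = field(default_factory=list)
    index: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    homolog_map: Dict[str, str] = field(default_factory=dict)
    general_words: FrozenSet[str] = DEFAULT_GENERAL_WORDS
    stop_words: FrozenSet[str] = DEFAULT_STOP_WORDS

    def add_entry(self, entry: DictionaryEntry) -> None:
        self.entries.append(entry)
        for name in entry.names:
            for key in expand_variants(name, self.general_words, self.stop_words):
                self.index.setdefault(key, set()).add((entry.namespace, entry.identifier))

    def lookup(self, key: str) -> Set[Tuple[str, str]]:
        return self.index.get(key, set())

    def lookup_text(self, text: str) -> Set[Tuple[str, str]]:
        """Union of index hits over all variants of ``text``."""
        hits: Set[Tuple[str, str]] = set()
        for key in expand_variants(text, self.general_words, self.stop_words):
            hits |= self.lookup(key)
        return hits

    def entry_for(self, namespace: str, identifier: str) -> Optional[DictionaryEntry]:
        for e in self.entries:
            if e.namespace == namespace and e.identifier == identifier:
                return e
        return None

    @property
    def max_key_tokens(self) -> int:
        return max((k.count(" ") + 1 for k in self.index), default=0)


REQUIRED_COLUMNS = ("namespace", "identifier", "name", "synonyms")


def load_dictionary(path: str | Path, entity_type: str, homolog_map: Optional[Dict[str, str]] = None) -> Lexicon:
    """Load a 4-column TSV (header required) into an indexed :class:`Lexicon`.

    Duplicate (namespace, identifier) rows are merged with a warning; the
    synonyms column is pipe-separated and may be empty.
    """
    if entity_type not in ENTITY_TYPES:
        raise ValueError(f"unknown entity type {entity_type!r}")
    path = Path(path)
    lex = Lexicon(entity_type=entity_type, homolog_map=dict(homolog_map or {}))
    rows: Dict[Tuple[str, str], DictionaryEntry] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return lex
        cols = header.split("\t")
        if tuple(c.strip() for c in cols[:4]) != REQUIRED_COLUMNS:
            raise DictionaryFormatError(
                f"{path}: line 1: expected columns {REQUIRED_COLUMNS}, got {cols}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DictionaryFormatError(f"{path}: line {lineno}: expected >= 3 columns")
            namespace, identifier, name = (p.strip() for p in parts[:3])
            if not identifier:
                raise DictionaryFormatError(f"{path}: line {lineno}: empty identifier")
            synonyms = tuple(
                s.strip() for s in (parts[3].split("|") if len(parts) > 3 and parts[3] else []) if s.strip()
            )
            synonyms = tuple(s for s in synonyms if s != name)
            key = (namespace, identifier)
            if key in rows:
                logger.warning("%s: line %d: duplicate entry %s merged", path, lineno, key)
                prev = rows[key]
                merged = prev.synonyms + tuple(s for s in (name,) + synonyms if s not in prev.names)
                rows[key] = DictionaryEntry(namespace, identifier, prev.preferred_name, merged, entity_type)
            else:
                rows[key] = DictionaryEntry(namespace, identifier, name, synonyms, entity_type)
    for entry in rows.values():
        lex.add_entry(entry)
    logger.info("%s: loaded %d entries, %d index keys", path, len(lex.entries), len(lex.index))
    return lex


def load_homolog_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV ``identifier<TAB>human_identifier``; no header."""
    out: Dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DictionaryFormatError(f"{path}: line {lineno}: expected 2 columns")
            out[parts[0].strip()] = parts[1].strip()
    return out
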