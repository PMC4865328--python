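"""Normalization of mentions to namespace identifiers.

Proteins use a two-rung disambiguation ladder: an unambiguous index hit is
accepted directly; when several identifiers match, each is mapped through the
homolog table to its human identifier and the mention is grounded only if a
single human identifier survives.  Other entity types use exact lookup only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from belpipe.lexicon import Lexicon
from belpipe.recognition import Mention


@dataclass(frozen=True)
class GroundedEntity:
    mention: Mention
    namespace: str
    identifier: str
    ambiguity_count: int
    resolution: str  # exact | homolog_to_human | unresolved

    def __post_init__(self):
        if self.resolution not in ("exact", "homolog_to_human", "unresolved"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if (self.resolution == "unresolved") != (self.identifier == ""):
            raise ValueError("identifier must be empty iff unresolved")
        if self.resolution == "exact" and self.ambiguity_count != 1:
            raise ValueError("exact resolution implies a single candidate")

    @property
    def resolved(self) -> bool:
        return self.resolution != "unresolved"


def _unresolved(mention: Mention, count: int) -> GroundedEntity:
    return GroundedEntity(mention, "", "", max(count, 1), "unresolved")


def ground(mention: Mention, lexicon: Lexicon) -> GroundedEntity:
    """Ground one mention against the lexicon of its entity type."""
    if mention.entity_type != lexicon.entity_type:
        raise ValueError(
            f"mention type {mention.entity_type!r} != lexicon type {lexicon.entity_type!r}"
        )
    candidates = sorted(lexicon.lookup_text(mention.text))
    if not candidates:
        return _unresolved(mention, 1)
    if len(candidates) == 1:
        ns, ident = candidates[0]
        return GroundedEntity(mention, ns, ident, 1, "exact")
    if lexicon.entity_type != "protein":
        return _unresolved(mention, len(candidates))
    humanized = {(ns, lexicon.homolog_map.get(ident, ident)) for ns, ident in candidates}
    if len(humanized) == 1:
        ns, ident = next(iter(humanized))
        return GroundedEntity(mention, ns, ident, len(candidates), "homolog_to_human")
    return _unresolved(mention, len(candidates))


def ground_all(mentions: List[Mention], lexicons: dict) -> List[GroundedEntity]:
    """Ground every mention using the lexicon matching its type; order preserved."""
    out = []
    for m in mentions:
        lex = lexicons.get(m.entity_type)
        out.append(ground(m, lex) if lex is not None else _unresolved(m, 1))
    return out
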