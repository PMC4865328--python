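"""Pattern-based assignment of molecular-activity function wraps.

A pattern is a token template mixing literal keywords with typed slots such
as ``<Protein>``; slots bind to grounded entities of that type.  Up to
``max_gap`` extra tokens may intervene between consecutive template elements
(so ``<Protein> activity`` matches "GK enzymatic activity" at gap 1).  An
entity receives at most one wrap; the first match in pattern-file order wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from belpipe.grounding import GroundedEntity
from belpipe.recognition import Token, tokenize

SLOT_TYPES = {
    "<Protein>": "protein",
    "<Chemical>": "chemical",
    "<Bioprocess>": "bioprocess",
    "<Disease>": "disease",
}
FUNCTIONS = ("act", "tscript", "complex", "deg", "pmod", "tloc")


@dataclass(frozen=True)
class FunctionPattern:
    function: str
    template: Tuple[str, ...]
    max_gap: int = 1
    pmod_type: Optional[str] = None

    def __post_init__(self):
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown function {self.function!r}")
        slots = [t for t in self.template if t in SLOT_TYPES]
        if not slots:
            raise ValueError("template must contain at least one slot")
        if self.function == "complex" and len(slots) < 2:
            raise ValueError("complex patterns need >= 2 slots")

    @property
    def slot_count(self) -> int:
        return sum(1 for t in self.template if t in SLOT_TYPES)


@dataclass(frozen=True)
class FunctionAssignment:
    """One wrap applied to one or more entities (several only for complex)."""

    entities: Tuple[GroundedEntity, ...]
    function: str
    pmod_type: Optional[str] = None


def load_patterns(path: str | Path) -> List[FunctionPattern]:
    """Read the pattern resource: ``function<TAB>template<TAB>max_gap[<TAB>pmod_type]``."""
    patterns: List[FunctionPattern] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            function = parts[0].strip()
            template = tuple(parts[1].split())
            max_gap = int(parts[2]) if len(parts) > 2 and parts[2].strip() else 1
            pmod_type = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
            patterns.append(FunctionPattern(function, template, max_gap, pmod_type))
    return patterns


def _entity_starting_at(
    entities: Sequence[GroundedEntity], tokens: Sequence[Token], idx: int, etype: str
) -> Optional[Tuple[GroundedEntity, int]]:
    """Entity of type ``etype`` whose span starts at token ``idx``; returns
    the entity and the index of the first token after it."""
    tok = tokens[idx]
    for ent in entities:
        m = ent.mention
        if m.entity_type != etype or m.start != tok.start:
            continue
        j = idx
        while j < len(tokens) and tokens[j].end <= m.end:
            j += 1
        return ent, j
    return None


def _match_at(
    pattern: FunctionPattern,
    tokens: Sequence[Token],
    entities: Sequence[GroundedEntity],
    start: int,
) -> Optional[Tuple[GroundedEntity, ...]]:
    """Try to match the template with element gaps <= max_gap, anchored at ``start``."""

    def rec(elem_idx: int, tok_idx: int, bound: Tuple[GroundedEntity, ...]):
        if elem_idx == len(pattern.template):
            return bound
        first = elem_idx == 0
        gaps = range(1) if first else range(pattern.max_gap + 1)
        for gap in gaps:
            ti = tok_idx + gap
            if ti >= len(tokens):
                return None
            elem = pattern.template[elem_idx]
            if elem in SLOT_TYPES:
                hit = _entity_starting_at(entities, tokens, ti, SLOT_TYPES[elem])
                if hit is not None:
                    ent, nxt = hit
                    result = rec(elem_idx + 1, nxt, bound + (ent,))
                    if result is not None:
                        return result
            else:
                if tokens[ti].text.lower() == elem.lower():
                    result = rec(elem_idx + 1, ti + 1, bound)
                    if result is not None:
                        return result
        return None

    return rec(0, start, ())


def classify_functions(
    sentence: str,
    entities: Sequence[GroundedEntity],
    patterns: Sequence[FunctionPattern],
) -> List[FunctionAssignment]:
    """Match every pattern against the token stream and wrap bound entities.

    Patterns are tried in file order, each anchored left-to-right; entities
    already carrying a wrap are not re-bound.
    """
    tokens = tokenize(sentence)
    wrapped: set = set()
    assignments: List[FunctionAssignment] = []
    for pattern in patterns:
        for start in range(len(tokens)):
            bound = _match_at(pattern, tokens, entities, start)
            if bound is None:
                continue
            key = tuple(id(e) for e in bound)
            if any(id(e) in wrapped for e in bound):
                continue
            assignments.append(FunctionAssignment(bound, pattern.function, pattern.pmod_type))
            wrapped.update(key)
    return assignments
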