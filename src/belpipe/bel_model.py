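"""Core BEL data types, canonicalization, and the statement parser/serializer.

The dialect is short-form BEL 1.0 restricted to what the pipeline emits:
abundance heads ``p``/``a``/``bp``/``path``, function wraps ``act``,
``tscript``, ``complex``, ``deg``, ``pmod``, ``tloc``, and the two causal
relations ``increases`` and ``decreases``.  ``pmod`` is modeled as a wrap
with a modification code but serialized BEL-1.0 style as an argument inside
the protein term, e.g. ``p(HGNC:AKT1,pmod(P))``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple

ABUNDANCE_HEADS = {
    "protein": "p",
    "chemical": "a",
    "bioprocess": "bp",
    "pathology": "path",
}
HEAD_TO_KIND = {v: k for k, v in ABUNDANCE_HEADS.items()}

NAMESPACES = frozenset({"HGNC", "EGID", "CHEBI", "GOBP", "MESHD"})
FUNCTION_WRAPS = frozenset({"act", "tscript", "complex", "deg", "pmod", "tloc"})
RELATIONS = ("increases", "decreases")


class BelValidationError(ValueError):
    """A term or statement violates a structural invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class BelParseError(ValueError):
    """Malformed BEL text; carries the character position of the failure."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at char {position})")


class UnsupportedConstructError(BelParseError):
    """Syntactically valid BEL using a head/wrap/relation outside the dialect."""


@dataclass(frozen=True)
class BelTerm:
    """An abundance node with an optional molecular-activity function wrap."""

    abundance_kind: str
    namespace: str
    value: str
    function_wrap: Optional[str] = None
    wrap_members: Tuple["BelTerm", ...] = ()
    pmod_type: Optional[str] = None

    def validate(self) -> None:
        if self.abundance_kind not in ABUNDANCE_HEADS:
            raise BelValidationError("abundance_kind", f"unknown kind {self.abundance_kind!r}")
        if self.namespace not in NAMESPACES:
            raise BelValidationError("namespace", f"unknown namespace {self.namespace!r}")
        if not self.value:
            raise BelValidationError("value", "must be nonempty")
        if self.function_wrap is not None and self.function_wrap not in FUNCTION_WRAPS:
            raise BelValidationError("function_wrap", f"unknown wrap {self.function_wrap!r}")
        if self.function_wrap == "complex":
            if len(self.wrap_members) < 2:
                raise BelValidationError("wrap_members", "complex requires >= 2 members")
            for m in self.wrap_members:
                m.validate()
        elif self.wrap_members:
            raise BelValidationError("wrap_members", "only complex wraps carry members")
        if self.pmod_type is not None and self.function_wrap != "pmod":
            raise BelValidationError("pmod_type", "only pmod wraps carry a modification code")

    @property
    def needs_quoting(self) -> bool:
        return bool(re.search(r"\s", self.value))


@dataclass(frozen=True)
class Provenance:
    """Where a statement came from and whether its polarity was flipped."""

    sentence_id: Optional[str] = None
    adjusted: bool = False


@dataclass(frozen=True)
class BelStatement:
    subject: BelTerm
    relation: str
    object: BelTerm
    provenance: Optional[Provenance] = field(default=None, compare=False)

    def validate(self) -> None:
        if self.relation not in RELATIONS:
            raise BelValidationError("relation", f"must be one of {RELATIONS}, got {self.relation!r}")
        self.subject.validate()
        self.object.validate()

    def flipped(self) -> "BelStatement":
        other = "decreases" if self.relation == "increases" else "increases"
        prov = self.provenance or Provenance()
        return replace(self, relation=other, provenance=replace(prov, adjusted=not prov.adjusted))


def _serialize_value(value: str) -> str:
    if re.search(r"\s", value):
        return '"' + value.replace('"', '\\"') + '"'
    return value


def _serialize_abundance(term: BelTerm) -> str:
    head = ABUNDANCE_HEADS[term.abundance_kind]
    inner = f"{term.namespace}:{_serialize_value(term.value)}"
    if term.function_wrap == "pmod":
        code = term.pmod_type or "P"
        return f"{head}({inner},pmod({code}))"
    return f"{head}({inner})"


def serialize_term(term: BelTerm) -> str:
    term.validate()
    if term.function_wrap is None or term.function_wrap == "pmod":
        return _serialize_abundance(term)
    if term.function_wrap == "complex":
        members = ",".join(serialize_term(m) for m in term.wrap_members)
        return f"complex({members})"
    return f"{term.function_wrap}({_serialize_abundance(term)})"


def serialize_statement(statement: BelStatement) -> str:
    """Render a statement as one line of BEL text."""
    statement.validate()
    return (
        f"{serialize_term(statement.subject)} {statement.relation} "
        f"{serialize_term(statement.object)}"
    )


class _Scanner:
    """Minimal tokenizer over one statement line."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise BelParseError(f"expected {ch!r}, found {self.peek()!r}", self.pos)
        self.pos += 1

    def word(self) -> str:
        m = re.match(r"[A-Za-z_][\w\-]*", self.text[self.pos :])
        if not m:
            raise BelParseError("expected identifier", self.pos)
        self.pos += m.end()
        return m.group(0)

    def value(self) -> str:
        if self.peek() == '"':
            start = self.pos
            self.pos += 1
            out = []
            while self.pos < len(self.text):
                c = self.text[self.pos]
                if c == "\\" and self.pos + 1 < len(self.text):
                    out.append(self.text[self.pos + 1])
                    self.pos += 2
                    continue
                if c == '"':
                    self.pos += 1
                    return "".join(out)
                out.append(c)
                self.pos += 1
            raise BelParseError("unterminated quoted value", start)
        m = re.match(r"[^\s(),:\"]+", self.text[self.pos :])
        if not m:
            raise BelParseError("expected value", self.pos)
        self.pos += m.end()
        return m.group(0)


def _parse_abundance(sc: _Scanner, head: str) -> BelTerm:
    kind = HEAD_TO_KIND[head]
    sc.expect("(")
    sc.skip_ws()
    namespace = sc.word()
    if namespace not in NAMESPACES:
        raise UnsupportedConstructError(f"unknown namespace {namespace!r}", sc.pos)
    sc.expect(":")
    sc.skip_ws()
    value = sc.value()
    sc.skip_ws()
    pmod_type = None
    wrap = None
    if sc.peek() == ",":
        sc.pos += 1
        sc.skip_ws()
        fn = sc.word()
        if fn != "pmod":
            raise UnsupportedConstructError(f"unsupported term argument {fn!r}", sc.pos)
        sc.expect("(")
        sc.skip_ws()
        pmod_type = sc.value()
        sc.skip_ws()
        sc.expect(")")
        sc.skip_ws()
        wrap = "pmod"
    sc.expect(")")
    return BelTerm(kind, namespace, value, function_wrap=wrap, pmod_type=pmod_type)


def parse_term(sc: _Scanner) -> BelTerm:
    sc.skip_ws()
    start = sc.pos
    head = sc.word()
    if head in HEAD_TO_KIND:
        return _parse_abundance(sc, head)
    if head == "complex":
        sc.expect("(")
        members = []
        while True:
            members.append(parse_term(sc))
            sc.skip_ws()
            if sc.peek() == ",":
                sc.pos += 1
                continue
            break
        sc.expect(")")
        if len(members) < 2:
            raise BelParseError("complex requires >= 2 members", start)
        kind = members[0].abundance_kind
        return BelTerm(kind, members[0].namespace, members[0].value,
                       function_wrap="complex", wrap_members=tuple(members))
    if head in FUNCTION_WRAPS:
        sc.expect("(")
        inner_head = sc.word()
        if inner_head not in HEAD_TO_KIND:
            raise UnsupportedConstructError(f"unsupported wrapped head {inner_head!r}", sc.pos)
        inner = _parse_abundance(sc, inner_head)
        if inner.function_wrap is not None:
            raise UnsupportedConstructError("nested wraps are not supported", sc.pos)
        sc.expect(")")
        return replace(inner, function_wrap=head)
    raise UnsupportedConstructError(f"unknown function or head {head!r}", start)


def parse_statement(text: str) -> BelStatement:
    """Parse one BEL statement line (inverse of :func:`serialize_statement`)."""
    sc = _Scanner(text)
    subject = parse_term(sc)
    sc.skip_ws()
    rel_start = sc.pos
    relation = sc.word()
    if relation not in RELATIONS:
        raise UnsupportedConstructError(f"unsupported relation {relation!r}", rel_start)
    obj = parse_term(sc)
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise BelParseError("trailing text after statement", sc.pos)
    stmt = BelStatement(subject, relation, obj)
    stmt.validate()
    return stmt


def _canonical_term(term: BelTerm) -> BelTerm:
    if term.function_wrap == "complex":
        members = tuple(sorted((_canonical_term(replace(m)) for m in term.wrap_members),
                               key=serialize_term))
        return replace(term, wrap_members=members,
                       namespace=members[0].namespace, value=members[0].value,
                       abundance_kind=members[0].abundance_kind)
    return term


def canonicalize(statement: BelStatement) -> str:
    """Deterministic equality key: normalized whitespace/quoting, sorted complex members."""
    statement.validate()
    canon = BelStatement(
        _canonical_term(statement.subject),
        statement.relation,
        _canonical_term(statement.object),
    )
    return serialize_statement(canon)


def read_bel_script(lines: Iterator[str]) -> list[Tuple[Optional[str], BelStatement]]:
    """Read BEL script lines; ``#`` comments and blank lines ignored.

    Lines may be prefixed with ``sentence_id<TAB>``; without a tab the
    sentence id is None.  Parse failures re-raise with the line number.
    """
    out = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        sentence_id: Optional[str] = None
        body = line
        if "\t" in line:
            sentence_id, body = line.split("\t", 1)
        try:
            stmt = parse_statement(body.strip())
        except BelParseError as exc:
            raise BelParseError(f"line {lineno}: {exc}", exc.position) from exc
        if sentence_id is not None:
            stmt = replace(stmt, provenance=Provenance(sentence_id=sentence_id))
        out.append((sentence_id, stmt))
    return out
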