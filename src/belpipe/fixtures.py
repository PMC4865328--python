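"""Packaged worked-example sentences and a synthetic corpus generator.

The worked-example bundle carries seven documented sentences with
hand-authored constituency trees (one deliberately awkward, to exercise
agent recovery above the grandparent level), mini-dictionaries covering every
gold identifier, and the gold statements.  The synthetic generator builds
sentences from a ``[trigger of] A verb B [and C]`` template with opaque
identifiers and computes gold statements from the template semantics,
including parity-correct polarity flips.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from belpipe import resources as res
from belpipe.bel_model import BelStatement, parse_statement, read_bel_script
from belpipe.function_classification import load_patterns
from belpipe.lexicon import DictionaryEntry, Lexicon, load_dictionary, load_homolog_map
from belpipe.relation_assembly import (
    PipelineResources,
    RelationKeywordMap,
    load_adjustment_keywords,
)
from belpipe.srl_svo import ParseTree, read_ptb

DictRow = Tuple[str, str, str, str]  # namespace, identifier, name, pipe-joined synonyms


@dataclass
class FixtureBundle:
    sentences: List[Tuple[str, str]]  # (sentence_id, text)
    trees: List[str]  # PTB lines, aligned by order
    dictionaries: Dict[str, List[DictRow]]  # entity_type -> rows
    homologs: List[Tuple[str, str]]
    gold: List[Tuple[str, str]]  # (sentence_id, BEL line)
    relation_verbs_text: str = field(default_factory=res.relation_verbs_text)
    adjustment_text: str = field(default_factory=res.adjustment_keywords_text)
    patterns_text: str = field(default_factory=res.function_patterns_text)

    def __post_init__(self):
        if len(self.sentences) != len(self.trees):
            raise ValueError("every sentence needs exactly one tree")

    # -- in-memory accessors -------------------------------------------------

    def lexicons(self) -> Dict[str, Lexicon]:
        homolog_map = dict(self.homologs)
        out: Dict[str, Lexicon] = {}
        for etype, rows in self.dictionaries.items():
            lex = Lexicon(entity_type=etype, homolog_map=homolog_map)
            for namespace, identifier, name, synonyms in rows:
                syns = tuple(s for s in synonyms.split("|") if s and s != name)
                lex.add_entry(DictionaryEntry(namespace, identifier, name, syns, etype))
            out[etype] = lex
        return out

    def resources(self) -> PipelineResources:
        from belpipe.function_classification import FunctionPattern

        patterns = [
            FunctionPattern(fn, tuple(t.split()), gap, pmod or None)
            for fn, t, gap, pmod in _parse_patterns_text(self.patterns_text)
        ]
        return PipelineResources(
            lexicons=self.lexicons(),
            patterns=patterns,
            relation_map=RelationKeywordMap(_parse_relation_text(self.relation_verbs_text)),
            adjustment=frozenset(_parse_keywords_text(self.adjustment_text)),
        )

    def parse_trees(self) -> List[ParseTree]:
        return [read_ptb(t, s) for t, (_, s) in zip(self.trees, self.sentences)]

    def gold_by_sentence(self) -> Dict[str, List[BelStatement]]:
        out: Dict[str, List[BelStatement]] = {sid: [] for sid, _ in self.sentences}
        for sid, line in self.gold:
            out.setdefault(sid, []).append(parse_statement(line))
        return out

    # -- directory serialization --------------------------------------------

    def write(self, directory: str | Path) -> Path:
        d = Path(directory)
        (d / "config").mkdir(parents=True, exist_ok=True)
        with (d / "sentences.jsonl").open("w", encoding="utf-8") as fh:
            for sid, text in self.sentences:
                fh.write(json.dumps({"sentence_id": sid, "text": text}) + "\n")
        (d / "trees.ptb").write_text("\n".join(self.trees) + "\n", encoding="utf-8")
        for etype, rows in sorted(self.dictionaries.items()):
            lines = ["namespace\tidentifier\tname\tsynonyms"]
            lines += ["\t".join(row) for row in rows]
            (d / f"dict_{etype}.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        (d / "homologs.tsv").write_text(
            "".join(f"{a}\t{b}\n" for a, b in self.homologs), encoding="utf-8"
        )
        (d / "gold.bel").write_text(
            "".join(f"{sid}\t{line}\n" for sid, line in self.gold), encoding="utf-8"
        )
        (d / "config" / "relation_verbs.tsv").write_text(self.relation_verbs_text, encoding="utf-8")
        (d / "config" / "adjustment_keywords.txt").write_text(self.adjustment_text, encoding="utf-8")
        (d / "config" / "function_patterns.tsv").write_text(self.patterns_text, encoding="utf-8")
        config = {
            "dictionaries": {e: f"dict_{e}.tsv" for e in sorted(self.dictionaries)},
            "homolog_map": "homologs.tsv",
            "patterns": "config/function_patterns.tsv",
            "relation_verbs": "config/relation_verbs.tsv",
            "adjustment_keywords": "config/adjustment_keywords.txt",
        }
        import yaml

        (d / "config" / "config.yaml").write_text(
            yaml.safe_dump(config, sort_keys=True), encoding="utf-8"
        )
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "FixtureBundle":
        d = Path(directory)
        sentences = []
        with (d / "sentences.jsonl").open(encoding="utf-8") as fh:
            for raw in fh:
                if raw.strip():
                    rec = json.loads(raw)
                    sentences.append((rec["sentence_id"], rec["text"]))
        trees = [l for l in (d / "trees.ptb").read_text(encoding="utf-8").splitlines() if l.strip()]
        dictionaries: Dict[str, List[DictRow]] = {}
        for path in sorted(d.glob("dict_*.tsv")):
            etype = path.stem[len("dict_") :]
            rows: List[DictRow] = []
            lines = path.read_text(encoding="utf-8").splitlines()
            for line in lines[1:]:
                if line.strip():
                    parts = line.split("\t")
                    parts += [""] * (4 - len(parts))
                    rows.append(tuple(parts[:4]))  # type: ignore[arg-type]
            dictionaries[etype] = rows
        homologs = []
        for line in (d / "homologs.tsv").read_text(encoding="utf-8").splitlines():
            if line.strip():
                a, b = line.split("\t")
                homologs.append((a, b))
        gold = []
        for line in (d / "gold.bel").read_text(encoding="utf-8").splitlines():
            if line.strip():
                sid, body = line.split("\t", 1)
                gold.append((sid, body))
        return cls(
            sentences=sentences,
            trees=trees,
            dictionaries=dictionaries,
            homologs=homologs,
            gold=gold,
            relation_verbs_text=(d / "config" / "relation_verbs.tsv").read_text(encoding="utf-8"),
            adjustment_text=(d / "config" / "adjustment_keywords.txt").read_text(encoding="utf-8"),
            patterns_text=(d / "config" / "function_patterns.tsv").read_text(encoding="utf-8"),
        )


def _parse_relation_text(text: str) -> Dict[str, str]:
    out = {}
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            lemma, rel = line.split("\t")
            out[lemma.strip().lower()] = rel.strip()
    return out


def _parse_keywords_text(text: str) -> List[str]:
    return [l.strip().lower() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def _parse_patterns_text(text: str) -> List[Tuple[str, str, int, str]]:
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        parts += [""] * (4 - len(parts))
        out.append((parts[0], parts[1], int(parts[2] or 1), parts[3]))
    return out


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

_PROTEIN_ROWS: List[DictRow] = [
    ("HGNC", "MAP3K1", "MAP3K1", "MEKK1"),
    ("HGNC", "AR", "AR", "androgen receptor"),
    ("HGNC", "PTGS2", "PTGS2", "COX2|COX-2"),
    ("HGNC", "IL1B", "IL1B", "IL-1 beta|IL-1beta"),
    ("HGNC", "IL6", "IL6", "IL-6"),
    ("HGNC", "TNF", "TNF", "tumor necrosis factor"),
    ("HGNC", "BCL2", "BCL2", ""),
    ("HGNC", "IL5", "IL5", "IL-5"),
    ("HGNC", "CSF2", "CSF2", "GM-CSF"),
    ("HGNC", "LCP1", "LCP1", "L-plastin"),
    ("HGNC", "GAPDH", "GAPDH", "Glyceraldehyde-3-phosphate dehydrogenase"),
    ("HGNC", "TPI1", "TPI1", "TPI|triosephosphateisomerase"),
    ("HGNC", "MBD3", "MBD3", ""),
    ("HGNC", "MBD2", "MBD2", ""),
    ("HGNC", "DNMT1", "DNMT1", ""),
    ("HGNC", "AQP7", "AQP7", "Aqp7"),
    ("HGNC", "GK", "GK", "glycerol kinase"),
    ("EGID", "3308", "heat shock protein family A (Hsp70) member 4", "Hsp70"),
    ("EGID", "3309", "heat shock protein family A (Hsp70) member 5", "Hsp70"),
]

_CHEMICAL_ROWS: List[DictRow] = [
    ("CHEBI", "testosterone", "testosterone", ""),
    ("CHEBI", "lipopolysaccharide", "lipopolysaccharide", "LPS"),
]

_BIOPROCESS_ROWS: List[DictRow] = [
    ("GOBP", "glycolysis", "glycolysis", ""),
    ("GOBP", "cell cycle", "cell cycle", ""),
]

_DISEASE_ROWS: List[DictRow] = [
    ("MESHD", "D011471", "prostate cancer", "prostatic neoplasms"),
    ("MESHD", "D001943", "breast cancer", "breast neoplasms"),
]

_WORKED: List[Tuple[str, str, str, List[str]]] = [
    (
        "s1",
        "MEKK1 also stimulates the transcription of the androgen receptor.",
        "(S (NP (NN MEKK1)) (ADVP (RB also)) (VP (VBZ stimulates) (NP (NP (DT the)"
        " (NN transcription)) (PP (IN of) (NP (DT the) (JJ androgen) (NN receptor))))) (. .))",
        ["p(HGNC:MAP3K1) increases tscript(p(HGNC:AR))"],
    ),
    (
        "s2",
        "Inhibition of COX2 markedly reduced both IL-1 beta and IL-6 release.",
        "(S (NP (NP (NN Inhibition)) (PP (IN of) (NP (NN COX2)))) (VP (ADVP (RB markedly))"
        " (VBD reduced) (NP (PDT both) (NP (NN IL-1) (NN beta)) (CC and)"
        " (NP (NN IL-6) (NN release)))) (. .))",
        [
            "p(HGNC:PTGS2) increases p(HGNC:IL1B)",
            "p(HGNC:PTGS2) increases p(HGNC:IL6)",
        ],
    ),
    (
        # two-verb sentence; the inner clause hides the verb under an extra VP
        # layer so the agent sits above the literal grandparent
        "s3",
        "TNF downregulated BCL2 whereas IL-5 or GM-CSF strongly upregulated BCL2 expression.",
        "(S (NP (NN TNF)) (VP (VP (VBD downregulated) (NP (NN BCL2))) (SBAR (IN whereas)"
        " (S (NP (NP (NN IL-5)) (CC or) (NP (NN GM-CSF))) (VP (ADVP (RB strongly))"
        " (VP (VBD upregulated) (NP (NN BCL2) (NN expression))))))) (. .))",
        [
            "p(HGNC:TNF) decreases p(HGNC:BCL2)",
            "p(HGNC:IL5) increases p(HGNC:BCL2)",
            "p(HGNC:CSF2) increases p(HGNC:BCL2)",
        ],
    ),
    (
        "s4",
        "L-plastin gene expression was positively regulated by testosterone in"
        " AR-positive prostate and breast cancer cells.",
        "(S (NP (NN L-plastin) (NN gene) (NN expression)) (VP (VBD was) (VP (ADVP (RB positively))"
        " (VBN regulated) (PP (IN by) (NP (NN testosterone))) (PP (IN in) (NP (JJ AR-positive)"
        " (NN prostate) (CC and) (NN breast) (NN cancer) (NNS cells))))) (. .))",
        ["a(CHEBI:testosterone) increases act(p(HGNC:AR))"],
    ),
    (
        "s5",
        "Glyceraldehyde-3-phosphate dehydrogenase (GAPDH) and triosephosphateisomerase"
        " (TPI) are essential to glycolysis.",
        "(S (NP (NP (NN Glyceraldehyde-3-phosphate) (NN dehydrogenase) (-LRB- -LRB-)"
        " (NN GAPDH) (-RRB- -RRB-)) (CC and) (NP (NN triosephosphateisomerase)"
        " (-LRB- -LRB-) (NN TPI) (-RRB- -RRB-))) (VP (VBP are) (ADJP (JJ essential)"
        " (PP (TO to) (NP (NN glycolysis))))) (. .))",
        [
            "act(p(HGNC:GAPDH)) increases bp(GOBP:glycolysis)",
            "act(p(HGNC:TPI1)) increases bp(GOBP:glycolysis)",
        ],
    ),
    (
        "s6",
        "Finally, the abundance of MBD3 was highest in the late S phase when the DNMT1"
        " is also most abundant, whereas the MBD2 level was largely constant throughout"
        " the cell cycle.",
        "(S (ADVP (RB Finally)) (, ,) (NP (NP (DT the) (NN abundance)) (PP (IN of)"
        " (NP (NN MBD3)))) (VP (VBD was) (ADJP (JJS highest)) (PP (IN in) (NP (DT the)"
        " (JJ late) (NN S) (NN phase))) (SBAR (WHADVP (WRB when)) (S (NP (DT the)"
        " (NN DNMT1)) (VP (VBZ is) (ADVP (RB also)) (ADJP (RBS most) (JJ abundant)))))"
        " (, ,) (SBAR (IN whereas) (S (NP (DT the) (NN MBD2) (NN level)) (VP (VBD was)"
        " (ADVP (RB largely)) (ADJP (JJ constant)) (PP (IN throughout) (NP (DT the)"
        " (NN cell) (NN cycle))))))) (. .))",
        ['bp(GOBP:"cell cycle") increases p(HGNC:MBD3)'],
    ),
    (
        "s7",
        "We demonstrated the enhanced glycerol kinase enzymatic activity in Aqp7-KO"
        " and -knockdown adipocytes.",
        "(S (NP (PRP We)) (VP (VBD demonstrated) (NP (NP (DT the) (JJ enhanced)"
        " (NN glycerol) (NN kinase) (JJ enzymatic) (NN activity)) (PP (IN in)"
        " (NP (NN Aqp7-KO) (CC and) (NN -knockdown) (NN adipocytes))))) (. .))",
        ["p(HGNC:AQP7) decreases act(p(HGNC:GK))"],
    ),
]


def worked_examples() -> FixtureBundle:
    """Deterministic bundle of the documented example sentences."""
    sentences = [(sid, text) for sid, text, _, _ in _WORKED]
    trees = [tree for _, _, tree, _ in _WORKED]
    gold = [(sid, line) for sid, _, _, lines in _WORKED for line in lines]
    return FixtureBundle(
        sentences=sentences,
        trees=trees,
        dictionaries={
            "protein": list(_PROTEIN_ROWS),
            "chemical": list(_CHEMICAL_ROWS),
            "bioprocess": list(_BIOPROCESS_ROWS),
            "disease": list(_DISEASE_ROWS),
        },
        homologs=[("15481", "3308")],
        gold=gold,
    )


# ---------------------------------------------------------------------------
# synthetic corpora
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticParams:
    pool_size: int = 30
    noise_fraction: float = 0.0
    p_trigger: float = 0.4
    p_second_object: float = 0.4

    def validate(self) -> None:
        if self.pool_size < 3:
            raise ValueError("pool_size must be >= 3")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if not 0.0 <= self.p_trigger <= 1.0 or not 0.0 <= self.p_second_object <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")


_INC_VERBS = [("increased", "increases"), ("stimulated", "increases"),
              ("induced", "increases"), ("upregulated", "increases")]
_DEC_VERBS = [("reduced", "decreases"), ("inhibited", "decreases"),
              ("suppressed", "decreases"), ("downregulated", "decreases")]
_NOISE_VERBS = ["discussed", "examined", "mentioned", "considered"]


def _synthetic_tree(trigger: bool, subj: str, verb: str, objects: Sequence[str]) -> str:
    if len(objects) == 1:
        obj_np = f"(NP (NN {objects[0]}))"
    else:
        obj_np = f"(NP (NP (NN {objects[0]})) (CC and) (NP (NN {objects[1]})))"
    if trigger:
        subj_np = f"(NP (NP (NN Inhibition)) (PP (IN of) (NP (NN {subj}))))"
    else:
        subj_np = f"(NP (NN {subj}))"
    return f"(S {subj_np} (VP (VBD {verb}) {obj_np}) (. .))"


def generate_synthetic(
    n: int, seed: int, params: Optional[SyntheticParams] = None
) -> FixtureBundle:
    """Template corpus with gold statements derived from the template semantics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or SyntheticParams()
    params.validate()
    rng = random.Random(seed)
    names = [f"GENE{i:03d}" for i in range(params.pool_size)]
    idents = {name: f"SYN{i:04d}" for i, name in enumerate(names)}
    rows: List[DictRow] = [("HGNC", idents[name], idents[name], name) for name in names]

    sentences: List[Tuple[str, str]] = []
    trees: List[str] = []
    gold: List[Tuple[str, str]] = []
    n_noise = int(round(n * params.noise_fraction))
    for i in range(n):
        sid = f"syn{i:04d}"
        noisy = i < n_noise
        subj, *objs = rng.sample(names, 3)
        objects = objs if rng.random() < params.p_second_object else objs[:1]
        trigger = rng.random() < params.p_trigger
        if noisy:
            verb, relation = rng.choice(_NOISE_VERBS), "increases"
        else:
            verb, relation = rng.choice(_INC_VERBS + _DEC_VERBS)
        if trigger:
            relation = "decreases" if relation == "increases" else "increases"
            text = f"Inhibition of {subj} {verb} {' and '.join(objects)}."
        else:
            text = f"{subj} {verb} {' and '.join(objects)}."
        sentences.append((sid, text))
        trees.append(_synthetic_tree(trigger, subj, verb, objects))
        for obj in objects:
            gold.append((sid, f"p(HGNC:{idents[subj]}) {relation} p(HGNC:{idents[obj]})"))
    return FixtureBundle(
        sentences=sentences,
        trees=trees,
        dictionaries={"protein": rows},
        homologs=[],
        gold=gold,
    )
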