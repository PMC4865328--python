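"""Built-in keyword and pattern resources.

The shipped inventories are seeds: regulation-event verb lemmas mapped to
increases/decreases, a small polarity-adjustment keyword list, and function
patterns covering the documented examples.  All three are written out as
editable config files by the fixture bundles and can be replaced per run.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Tuple

# verb lemma -> relation; regulation + positive_regulation families map to
# increases, negative_regulation family to decreases
DEFAULT_RELATION_VERBS: Dict[str, str] = {
    # increases
    "stimulate": "increases",
    "increase": "increases",
    "induce": "increases",
    "enhance": "increases",
    "upregulate": "increases",
    "up-regulate": "increases",
    "promote": "increases",
    "activate": "increases",
    "regulate": "increases",
    "elevate": "increases",
    "augment": "increases",
    "trigger": "increases",
    "mediate": "increases",
    # decreases
    "reduce": "decreases",
    "decrease": "decreases",
    "inhibit": "decreases",
    "suppress": "decreases",
    "downregulate": "decreases",
    "down-regulate": "decreases",
    "repress": "decreases",
    "attenuate": "decreases",
    "block": "decreases",
    "abolish": "decreases",
    "impair": "decreases",
    "diminish": "decreases",
}

DEFAULT_ADJUSTMENT_KEYWORDS: FrozenSet[str] = frozenset(
    {
        "inhibition",
        "mutant",
        "inactivation",
        "knockdown",
        "knockout",
        "deficiency",
        "loss",
        "silencing",
        "depletion",
        "ablation",
    }
)

# function, template, max_gap, pmod_type ('' = none); order is tie-break order
DEFAULT_FUNCTION_PATTERNS: List[Tuple[str, str, int, str]] = [
    ("act", "<Protein> activity", 1, ""),
    ("act", "activity of <Protein>", 1, ""),
    ("act", "activation of <Protein>", 1, ""),
    ("tscript", "transcription of <Protein>", 1, ""),
    ("tscript", "<Protein> transcription", 1, ""),
    ("complex", "<Protein> / <Protein> complex", 0, ""),
    ("deg", "<Protein> degradation", 1, ""),
    ("deg", "degradation of <Protein>", 1, ""),
    ("pmod", "phosphorylation of <Protein>", 1, "P"),
    ("pmod", "<Protein> phosphorylation", 1, "P"),
    ("tloc", "translocation of <Protein>", 1, ""),
    ("tloc", "<Protein> translocation", 1, ""),
]


def relation_verbs_text() -> str:
    lines = ["# lemma<TAB>relation"]
    lines += [f"{lemma}\t{rel}" for lemma, rel in DEFAULT_RELATION_VERBS.items()]
    return "\n".join(lines) + "\n"


def adjustment_keywords_text() -> str:
    return "\n".join(["# one polarity-flip keyword per line"] + sorted(DEFAULT_ADJUSTMENT_KEYWORDS)) + "\n"


def function_patterns_text() -> str:
    lines = ["# function<TAB>template<TAB>max_gap<TAB>pmod_type"]
    for fn, template, gap, pmod in DEFAULT_FUNCTION_PATTERNS:
        lines.append(f"{fn}\t{template}\t{gap}\t{pmod}")
    return "\n".join(lines) + "\n"


def default_relation_map():
    from belpipe.relation_assembly import RelationKeywordMap

    return RelationKeywordMap(dict(DEFAULT_RELATION_VERBS))


def default_patterns():
    from belpipe.function_classification import FunctionPattern

    return [
        FunctionPattern(fn, tuple(template.split()), gap, pmod or None)
        for fn, template, gap, pmod in DEFAULT_FUNCTION_PATTERNS
    ]
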