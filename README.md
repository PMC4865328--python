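# belpipe

Rule-based extraction of Biological Expression Language (BEL) statements from
single biomedical sentences, plus a four-level scorer for comparing predicted
and gold statements.

The pipeline has four stages:

1. **Entity recognition** — greedy leftmost-longest dictionary matching over
   token n-grams for proteins, chemicals, biological processes and diseases,
   with a plug-in seam for externally produced mentions and configurable
   overlap resolution across recognizers.
2. **Entity normalization** — heuristic surface normalization (lowercasing,
   hyphen/period removal, species-prefix and plural stripping, parenthesis
   rewrites, space/general-word/stop-word removal) to ground mentions to
   namespace identifiers (HGNC/EGID/CHEBI/GOBP/MESHD); ambiguous protein
   mentions are disambiguated through a homolog-to-human identifier table.
3. **Function classification** — token-template patterns with typed slots
   assign molecular-activity wraps (`act`, `tscript`, `complex`, `deg`,
   `pmod`, `tloc`) to grounded entities.
4. **Relation classification** — a rule-based syntactic labeler recovers
   agent/patient arguments for relation verbs from Penn-Treebank constituency
   parses, the resulting subject–verb–object tuples are mapped to
   `increases`/`decreases` statements (cross product of the entities inside
   the subject and object phrases), and context keywords such as
   "inhibition" flip the polarity with odd/even parity.

The scorer compares statements per sentence at four granularities: term
(identifiers only), function (identifier + wrap), relation
(identifiers + relation type) and full BEL statement.

## Command line

```bash
# materialize the packaged worked-example bundle (sentences, trees,
# dictionaries, keyword/pattern configs, gold statements)
belpipe fixtures out/worked --worked-examples

# or generate a synthetic corpus with known gold structure
belpipe fixtures out/syn --synthetic --n 50 --seed 1

# run the pipeline
belpipe extract \
    --sentences out/worked/sentences.jsonl \
    --trees out/worked/trees.ptb \
    --config out/worked/config/config.yaml \
    --out pred.bel

# score at all four levels (or --level bel etc.)
belpipe evaluate --gold out/worked/gold.bel --pred pred.bel
```

File formats are plain text throughout: sentences as JSON Lines
(`sentence_id`, `text`), parse trees as one bracketed Penn-Treebank tree per
line aligned by record order, dictionaries as 4-column TSV
(`namespace identifier name synonyms`, synonyms pipe-separated), gold and
predicted statements as `sentence_id<TAB>BEL` lines, and keyword/pattern
resources as commented TSV/line-per-entry files.

## Library

```python
from belpipe.fixtures import worked_examples
from belpipe.relation_assembly import extract_statements
from belpipe.bel_model import serialize_statement

bundle = worked_examples()
resources = bundle.resources()
for (sid, text), tree in zip(bundle.sentences, bundle.parse_trees()):
    for stmt in extract_statements(text, tree, resources, sentence_id=sid):
        print(sid, serialize_statement(stmt))
```

## Scope notes

Only `increases`/`decreases` statements are modeled, and the statistical
components the original approach combined (CRF entity taggers, the
MLN/maximum-entropy role labelers) are represented by plug-in seams that
consume pre-computed mention and predicate–argument records rather than by
retrained models.
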