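# litmine

Sentence-level co-occurrence mining of biomedical abstract corpora.

`litmine` turns a corpus of abstracts (MEDLINE/PubMed XML or plain JSONL)
into scored, significance-tested association tables and filtered networks
between four entity types — genes, diseases, drugs, and cell types. It is
aimed at target-identification work: ranking disease-associated genes by
literature evidence, validating those rankings against clinically developed
targets, and exploring the resulting association graphs.

## What it computes

Entity mentions are found by dictionary matching against a typed concept
vocabulary (CUI, canonical name, aliases) and normalized by character-3gram
TF-IDF cosine similarity, so spelling variants land on the same concept. A
pair of concepts (x, y) of types X and Y co-occurs when both appear in the
same sentence. With C_xy the number of co-mention sentences, C_x\* and C_\*y
the per-entity margins (sentences containing x together with *any* Y entity,
and vice versa), and C_\*\* the total number of mixed-type sentences, each
pair receives the association score

```
S_xy = C_xy^a * (C_xy * C_** / (C_x* * C_*y))^(1-a),    a = 0.6 by default
```

which corrects the raw count by the background frequency of each entity:
heavily studied entities need more co-mentions to reach the same score.
Significance is the upper tail of a hypergeometric test (population C_\*\*,
successes C_x\*, draws C_\*y, observed C_xy) with Benjamini–Hochberg
adjustment within each type-pair family. Networks keep edges with adjusted
p ≤ 0.05 (configurable), weighted by score.

Validation utilities include Fisher's exact test (one-sided, with both the
sample and the conditional-MLE odds ratio) for clinical-target enrichment,
and a from-scratch GSEA-preranked implementation (weighted running-sum ES,
permutation NES, nominal p, FDR q). Relation-extraction scaffolding
($gene/$disease masking, the seven-label gene-disease taxonomy, pluggable
classifier contract, per-gene label aggregation) is included; the bundled
keyword classifier only exercises the pipeline and is not a trained model.

A synthetic-corpus generator plants associations of known lift into
template sentences, so the whole chain is testable without downloads.

## Worked example

Generate the canonical synthetic condition (200 genes × 20 diseases, 5,000
sentences, 10 planted gene–disease pairs at lift 20), annotate, count, and
score:

```python
from litmine import EntityType, annotate_corpus, count_cooccurrences, score_table
from litmine.assoc import records_to_frame
from litmine.synth import default_recovery_spec, generate_corpus, generate_vocabulary

spec = default_recovery_spec(seed=1)
vocab = generate_vocabulary(spec)
docs, truth = generate_corpus(spec, vocab)
sentences = list(annotate_corpus(docs, vocab))
table = count_cooccurrences(sentences, (EntityType.GENE, EntityType.DISEASE))
names = {cui: c.name for cui, c in vocab.concepts.items()}
records = score_table(table, names=names)
print(f"{len(docs)} documents, {len(sentences)} sentences, "
      f"{table.c_total} mixed-type sentences, {len(records)} associations")
frame = records_to_frame(records[:5])
print(frame[["name_x", "name_y", "count", "score", "p_value", "p_adj"]]
      .assign(score=lambda f: f.score.round(2)).to_string(index=False))
```

prints

```
1000 documents, 5000 sentences, 4163 mixed-type sentences, 2508 associations
  name_x      name_y  count  score      p_value        p_adj
GENE0004 DISEASE0004     24  18.23 1.402227e-22 3.516785e-19
GENE0007 DISEASE0007     23  16.98 4.463406e-20 5.597111e-17
GENE0009 DISEASE0009     21  16.21 4.433261e-18 3.706206e-15
GENE0003 DISEASE0003     22  15.65 2.249940e-17 1.410712e-14
GENE0000 DISEASE0000     20  15.13 1.783425e-16 8.945660e-14
```

All five top-ranked pairs are planted pairs: a background pair averages one
co-mention sentence, the planted pairs average twenty, and the score and
hypergeometric test pull them to the top of 2,508 observed pairs.

The same stages are available as a CLI:

```
litmine simulate --out corpus.jsonl --vocab vocab.tsv --truth truth.tsv
litmine annotate --corpus corpus.jsonl --vocab vocab.tsv --out ann.jsonl
litmine count    --annotations ann.jsonl --type-pair GENE-DISEASE --out counts/
litmine score    --counts counts/ --vocab vocab.tsv --out assoc.tsv
litmine network  --assoc assoc.tsv --padj 0.05 --out net.graphml
litmine run      --config config.yaml      # all of the above from one YAML
```

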