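# Methods

## Model and procedure

`litmine` treats the sentence as the unit of association evidence: two
concepts are associated to the extent that they are co-mentioned in more
sentences than their individual literature presence would predict.
The pipeline has five stages.

**1. Corpus ingestion and segmentation.** Abstracts come from MEDLINE/PubMed
XML (`PubmedArticle` records; multiple `AbstractText` sections joined with a
single space, titles opt-in) or JSONL. Sentence segmentation is a
deterministic rule: split on a run of `.?!` followed by whitespace and an
uppercase letter or digit, unless the preceding text ends in a listed
abbreviation ("e.g.", "i.e.", "et al.", "Fig.", "vs.", …). Offsets are
0-based half-open code-point indices and segmentation is a partition of the
text, so every downstream artifact is reproducible byte for byte. A
rule-based splitter was chosen over an NLP library's statistical one
deliberately: bit-stability across environments matters more here than
matching any particular tokenizer's notion of a sentence.

**2. Recognition and normalization.** The default tagger is a dictionary
matcher over the vocabulary's alias set: greedy longest match on token
boundaries, overlaps resolved longest-span-first then leftmost.  Matching is
case-insensitive for aliases of length ≥ 4 and case-sensitive below that, so
short gene symbols ("GBA") are not swallowed by common words. Normalization
is cosine similarity between character-3gram TF-IDF vectors: every alias is
padded with one `#` boundary marker per side, vectorized with smoothed
log-IDF over the alias collection and L2-normalized (one matrix row per
(alias, concept) pair). The best of the top-k candidates at or above the
threshold wins; ties go to the lexicographically smallest CUI. Defaults
k = 5 and threshold = 0.7 prefer precision; mentions that fail to link are
dropped from counting. The search is exact — at vocabulary fixture scale,
approximate nearest-neighbour indexing is purely an optimization and would
not change results. Neural taggers can replace the dictionary matcher
through the `tagger` seam of `annotate_corpus` (sentence text → typed raw
spans); nothing downstream changes.

**3. Counting.** For an ordered type pair (X, Y), a sentence containing at
least one linked X mention and one linked Y mention contributes exactly 1 to
C_\*\*, 1 to C_x\* for each distinct x, 1 to C_\*y for each distinct y, and
1 to C_xy for each distinct pair — multiplicity within a sentence is
ignored, since the evidence unit is "a sentence that contains" the pair.
Whether counting should instead be per mention pair is genuinely open; the
per-sentence dedup reading is recorded here as the package's assumption.
Tables over disjoint corpora merge by entrywise addition, which is what
makes incremental (e.g. monthly) corpus updates equal to a full recount.

**4. Scoring and significance.**

    S_xy = C_xy^a · (C_xy · C_** / (C_x* · C_*y))^(1−a)

with a ∈ [0, 1], default 0.6. At a = 1 the score is the raw count; at a = 0
it is the pure background ratio (observed/expected under independence); the
default leans toward the count while still demoting pairs whose co-mentions
are explained by one heavily studied entity. S is zero iff the count is
zero, strictly increasing in C_xy, and strictly decreasing in either margin.
Significance is the upper hypergeometric tail P(X ≥ C_xy) with population
C_\*\*, successes C_x\*, draws C_\*y, computed via the scipy survival
function (stable for the small tail probabilities that large corpora
produce). Only observed pairs (C_xy ≥ 1) are tested; the Benjamini–Hochberg
family is the set of observed pairs of that type pair, since untested
zero-count pairs carry no evidence either way. Full float precision is
persisted; reports may round scores to two decimals.

**5. Networks.** Records from any union of type pairs form one undirected
graph (co-occurrence is symmetric); edges require adjusted p ≤ threshold
(default 0.05) and are weighted by score. Ego subgraphs of a chosen radius
support neighborhood views around one concept. Exports (GraphML, TSV edge
list) sort nodes and edges by CUI, so repeated exports are byte-identical.

**Relation scaffolding.** Sentence-level gene–disease relation labels use a
closed seven-value taxonomy (no explicit relationship; plays a role; target
general / causative / modulator-decrease / modulator-increase; biomarker).
Before classification, every mention of the pair's gene concept is replaced
by `$gene` and every disease mention by `$disease`; masking is exhaustive
and invertible. The classifier is an injected dependency (masked text → one
label); training and shipping a transformer fine-tune is out of scope for
this package, so the bundled `KeywordRuleClassifier` is a documented
keyword table that exists only to exercise the contract — its output is not
a scientific claim. When a sentence contains several gene or disease
mentions, one masked instance is produced per (gene, disease) pair.
Per-gene aggregation reports the percentage of sentences per label (one
decimal) for genes with at least `min_sentences` (default 50) supporting
sentences.

**Enrichment validation.** The Fisher test builds the 2×2 table (a = mined ∩
targets, b = mined only, c = targets only, d = remainder of the gene
universe) and reports the one-sided "greater" p — numerically identical to
the co-occurrence hypergeometric tail — plus two odds-ratio estimates: the
sample cross-product ratio a·d/(b·c) and the conditional MLE, found by
root-finding (tolerance 1e-8, on the log-odds scale) for the Fisher
noncentral hypergeometric odds parameter whose conditional mean of cell *a*
equals the observed *a*; for this exponential family the mean-matching root
is the conditional likelihood maximizer. Both estimates are always emitted
because the two conventions differ in the literature and on moderate tables
the difference is visible at the second decimal.

GSEA-preranked is implemented from its definition: hits increment the
running sum by |metric|^w normalized over the set's hits (w default 1),
misses decrement by 1/N_miss, and the ES is the extremum of largest
magnitude — evaluated only immediately before/after hits, where the extrema
must lie. Null ES values come from gene-label permutations (equivalent to
random same-size sets); NES divides ES by the mean same-sign permutation
ES, nominal p is the same-sign permutation tail fraction, and FDR q is the
ratio of the pooled-permutation NES tail fraction to the observed NES tail
fraction, clipped to [0, 1]. Each gene set consumes an independent RNG
stream spawned from the single seed, so results are deterministic and
insensitive to set order. Defaults: weight 1, 1,000 permutations, seed 17.

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical* structure the pipeline measures:
per-sentence entity co-mentions at a controlled background rate, planted
pairs boosted by a lift λ, optional Zipf (exponent 1) popularity weights to
mimic the skewed margins of real literature (rare versus heavily studied
diseases), and optional typo mode substituting each concept's
misspelling-variant alias (second/third characters transposed) to exercise
the 3-gram linker. Per-pair co-mention counts are drawn
Binomial(n_sentences, rate) and placed in distinct sentence slots, so each
sentence hosts at most one generated pair and the per-pair co-mention
probability is exactly the specified rate. Sentences come from fixed typed
templates, giving the dictionary tagger exact recall.

Consequently, passing tests demonstrate the correctness of counting,
scoring, testing, and ranking under known truth — they do not demonstrate
NER/NEN quality on free text, robustness to negation, hedging, coreference,
or abbreviation ambiguity, none of which the templates contain.

The canonical recovery condition (`default_recovery_spec`): 200 genes × 20
diseases, 5,000 sentences, base rate 1/5,000 (a background pair averages
one co-mention sentence), 10 planted pairs at lift 20 (expected count 20),
seed 1. These sizes keep a full generate–annotate–count–score cycle under a
few seconds while leaving ~2,500 observed background pairs for the
false-positive calibration.

## Numerical choices and degenerate inputs

- Hypergeometric inputs are validated (0 ≤ k ≤ min(K, n), K, n ≤ N); k = 0
  short-circuits to p = 1.
- BH adjustment delegates to the standard step-up implementation and is
  checked against a naive reference; empty input returns empty.
- Cosine similarities are clipped at 1.0 against rounding; self-links are
  exact to 1e-9.
- Conditional-MLE odds ratio: boundary cells (observed count at the support
  edge) return 0 or ∞ without root-finding; bracket expansion stops at
  |log OR| = 500.
- GSEA: a set with no overlap is flagged not evaluable (NaN scores); a set
  covering the whole list is an error (no misses to decrement); an all-zero
  metric vector falls back to uniform hit weights.
- Scoring rejects inconsistent count tuples (e.g. C_xy > C_x\*) rather than
  silently producing a value.
- Ambiguous surfaces passing the link threshold for several entity types
  yield one mention per passing type; otherwise the higher-similarity type
  wins by construction of the per-type link.

## Known limitations

- Dictionary NER bounds recall by the alias list; there is no abbreviation
  expansion or coreference resolution.
- The keyword relation classifier is a placeholder; label percentages from
  it characterize the pipeline plumbing, not biology.
- The hypergeometric null treats sentences as exchangeable; it ignores
  document-level clustering of mentions and publication quality.
- GSEA FDR uses the standard pooled-permutation estimate, which is noisy
  for very small set collections; nominal p granularity is 1/n_perm.
- Corpus-scale behaviours (multi-million-sentence margins) are only
  represented in scaled-down form by the synthetic conditions.
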