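# Methods

## Problem and model

zhengnet mines abstract corpora for the genes associated with a TCM
syndrome, combining two independent evidence tracks and intersecting them.
The pipeline assumes (i) a closed gene vocabulary (a curated dictionary of
canonical symbols and synonyms, in the spirit of a neuro-endocrine-immune
gene list), (ii) a knowledge base of known gene–gene relations usable as
distant supervision, and (iii) a symptom classification per syndrome
curated by domain experts. Everything downstream is determined by these
inputs plus a seed.

### Gene entity recognition

Abstracts are split into sentences by terminal punctuation with an
abbreviation blocklist ("Fig.", "e.g.", "et al.", ...), then tokenized by
a rule-based English tokenizer that splits on whitespace and punctuation
but preserves word-internal hyphens/slashes, so `IL-10` and `HLA-DRB1` are
single tokens. Token n-grams are matched against the dictionary longest
match first, leftmost on ties; matching is case-insensitive by default.
Short surfaces (≤ 3 characters) whose case-folded form is a common English
word (`INS`, `MET`, `AR`, ...) require an exact-case match — these symbols
otherwise produce systematic false positives in prose. The exception list
is configurable per dictionary.

The method is segmenter-agnostic dictionary matching: any tokenizer that
yields stable offsets would serve; the built-in one is chosen for
determinism and zero dependencies.

### Relation extraction (sparse multi-instance learning)

One bag per unordered gene pair co-mentioned anywhere in the corpus;
instances are the pair's co-mention sentences, with an abstract-level
fallback (the two mention sentences joined) when a pair shares an abstract
but never a sentence. Bags are flagged 1 iff the pair is in the knowledge
base — distant supervision in place of manual annotation, on the premise
that a specific relation is typically asserted in few sentences (sparse
evidence) while co-mention is common.

Instance features: presence-coded bag-of-words over the tokens between the
two mentions plus a 3-token window on each side (vocabulary fit on
training bags; unseen tokens map to one reserved OOV feature), a one-hot
token-distance bucket (≤2, 3–5, 6–10, >10 tokens between mentions), and a
relation-cue-lexicon bit (default lexicon: "activates", "inhibits",
"binds", "phosphorylates", "regulates", "suppresses", "induces",
"stabilizes" and close variants).

The classifier scores instances linearly and pools with log-mean-exp
(a smooth maximum): `z(B) = log mean_i exp(w·x_i + b)`, bag probability
`σ(z)`. Training minimizes bag-level logistic loss by full-batch proximal
gradient descent (learning rate 0.5, 300 iterations, zero initialization)
with soft-thresholding for the L1 penalty (λ = 0.01, bias unpenalized).
Zero initialization and full batches make training exactly deterministic;
the seed parameter is recorded for provenance and reserved for stochastic
variants. Decision threshold 0.5 by default. The final network edges are
taken from model predictions; `edges_from="flags"` reproduces the
alternative reading where flag-positive bags become edges directly.

### Network scoring

The gene network is undirected, deduplicated, without self-loops or
isolated nodes. Communities come from seeded Louvain modularity
maximization, ordered by descending size then smallest member symbol.

Centralities, all scaled into [0, 1]:

- **CD** degree / max degree;
- **CB** normalized betweenness / max betweenness (0 when all betweenness
  is 0);
- **CC** Freeman closeness within each connected component, divided by the
  global maximum;
- **CE** eigenvector centrality per component, scaled so the component's
  hub gets 1 (cross-component eigenvector magnitudes are not comparable;
  two-node components get 1 for both members, the symmetric solution).

Max-scaling is chosen so the top gene in each index scores exactly 1,
matching how the reference worked examples are normalized; raw Freeman
values are one division away if needed. Centralities are computed on the
whole network rather than per sub-network, since the final ranking
compares genes across the full gene set.

Composite scores: `CMI = CD·CB·(1/CC) + CE`, with the product term defined
as 0 whenever CB = 0 (a node on no shortest path contributes only its hub
score; this also neutralizes the 1/CC singularity, which can otherwise
arise only for the degenerate single-node network where CD = CB = 0,
CC = 0, CE = 1 by contract). `SW = N + ZJW` per sub-network, where ZJW is
a free nonnegative expert-relevance input (default 0, so SW ordering
defaults to size ordering); `ZSW = (SW − MIN)/(MAX − MIN)` min-max over
the sub-networks of one network, defined as 1 for every sub-network when
MAX = MIN (consistent with the single-community limit); `GW = CMI + ZSW`.
The emitted table satisfies GW − CMI − ZSW = 0 identically and breaks GW
ties by symbol.

### Combination method

`hit(s, g)` counts documents containing symptom term `s` (case-insensitive
contiguous token-subsequence, so "chest pain" never matches inside
"chestpain") and at least one mention of gene `g`. Symptoms whose gene set
is empty at `min_hits` (default 1) are pruned into `removed_terms`;
pruning a whole group is an error. Combinations are the Cartesian product
of one option per group — an option is a term or a tuple of terms that
always co-occur, which is how the stroke classification's paired symptoms
are encoded — with fixed terms inserted between the Qi-deficiency and
blood-stasis slots, matching the reference layout. Within a combination
gene sets are united ("the genes existing in each combination" — the union
reading is the one consistent with the large per-syndrome gene counts the
method is meant to produce); across combinations they are intersected.
The strict within-combination intersection is available via
`within="intersection"`.

### Integration

Matched set = decomposition ∩ combination per syndrome; shared set =
intersection of matched sets across diseases. Empty results are valid
outcomes, reported rather than raised. Over-representation uses the exact
hypergeometric upper tail (`P(X ≥ k)`) against a user universe, with
Benjamini–Hochberg adjustment across sets; raw p-values are always
emitted alongside.

The `IntegrationReport` records the seed and a SHA-256 hash of the full
input configuration, sufficient to re-run bit-identically. Stage timings
are logged to stderr but deliberately kept out of the serialized report so
that identical configuration and seed yield byte-identical report files.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the pipeline relies on:
planted gene mentions in templated subject–verb–object sentences,
knowledge-base pairs co-mentioned at `comention_rate_kb = 0.3` per
abstract versus `comention_rate_bg = 0.02` for background pairs (a 15×
planted signal), cue verbs on true-relation sentences with
`cue_rate = 0.9`, and Poisson(`hits_lambda = 2`) symptom–gene hit counts
with a fixed 20% of symptoms forced to zero genes to exercise the pruning
path. Standard evaluation conditions: 20 genes, 400 abstracts, knowledge
base covering 15% of pairs. Each generator draws from its own RNG stream
(master seed + CRC32 of the stream name), so adding a generator never
perturbs the others, and all outputs are byte-reproducible for a fixed
seed.

It does **not** emulate real abstract prose, MeSH indexing, ambiguous or
nested gene names, organism context, or realistic knowledge-base score
distributions. Consequently, passing tests demonstrate that the machinery
is correct (NER has precision and recall 1 on planted surfaces *by
construction*; the MIL classifier recovers a cleanly planted cue signal
with held-out AUC ≈ 1), not that the pipeline achieves any particular
accuracy on live literature, where dictionary NER and distant supervision
are both noisy.

## Problem sizes and numerical choices

The test-suite and verification script use desk-scale problems chosen as
the package's standard conditions: bag-construction oracle equivalence on
100 corpora of 8 genes × 20 abstracts; relation recovery over 10 seeds of
the standard 20 × 400 configuration; centrality oracles on 200 random
graphs of ≤ 8 nodes (exhaustive shortest-path and dense-eigenvector
recomputation); modularity brute force over all partitions of 6 nodes;
exact hypergeometric summation on universes ≤ 50.

Tolerances: centrality agreement at 1e-9 (two independent floating-point
routes); hypergeometric agreement at 1e-12 (float vs exact rationals);
score identities at 1e-9. Ties: lexicographic on gene symbols throughout;
communities ordered by size then smallest member. Degenerate inputs have
documented contracts rather than exceptions where a value is defensible
(single-node centralities, MAX = MIN normalization, empty matched sets);
genuinely ill-posed inputs (CC = 0 with CB > 0, negative ZJW, single-class
training sets, emptied symptom groups) raise typed errors.

## Known limitations

- Ten of the twenty reference worked-example rows carry composite scores
  that their own rounded centrality columns do not reproduce under the
  formula; the fixtures retain them only for the GW-identity check, and
  `datasets.FORMULA_CONSISTENT_GENES` lists the rows usable as formula
  fixtures. One reference hub value (1.01) exceeds the nominal [0, 1]
  scale; profiles are not clamped, so such inputs pass through unchanged.
- The MIL classifier is a linear sparse reduction; it is pluggable but no
  non-linear or neural alternative ships.
- No gene-symbol disambiguation beyond the exact-case list; no relation
  typing (activation vs inhibition); no cross-sentence coreference.
- Expert inputs (ZJW scores, symptom classifications, term grouping into
  options) are configuration, not inference: the package enumerates and
  scores what experts declare.
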