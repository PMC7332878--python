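# zhengnet

Literature-mining pipeline for discovering the genes behind a traditional
Chinese medicine (TCM) syndrome (*zheng*) — here, Qi deficiency and blood
stasis as it presents in coronary heart disease and in stroke — from
biomedical abstract corpora, with no reliance on live web services.

The TCM principle of *treating different diseases with the same method*
predicts that two diseases sharing a syndrome share molecular machinery.
zhengnet operationalizes that as set intersection over gene sets mined by
two independent tracks:

**Decomposition track** — dictionary-based gene NER over sentence-segmented
abstracts; distant-supervision multi-instance relation extraction (one *bag*
of evidence sentences per co-mentioned gene pair, labeled by knowledge-base
membership, scored by an L1-sparse instance classifier with smooth-max
pooling); an undirected gene network from the positive pairs, decomposed
into Louvain communities and ranked by

```
CMI = CD · CB · (1/CC) + CE        composite centrality per gene
SW  = N + ZJW                      sub-network weight (size + expert score)
ZSW = (SW − MIN) / (MAX − MIN)     min-max normalized across sub-networks
GW  = CMI + ZSW                    final gene weight
```

with CD/CB/CC/CE the max-scaled degree, betweenness, closeness and
eigenvector (hub) centralities.

**Combination track** — per-symptom gene *hits* (documents co-mentioning a
gene and a symptom term), enumeration of symptom combinations
(main × Qi-deficiency × blood-stasis options, fixed terms in every
combination, zero-gene symptoms pruned), and intersection of the
per-combination gene unions.

Per syndrome the two tracks are matched by intersection; across diseases
the matched sets are intersected again to yield the shared genes. A
hypergeometric over-representation analysis (Benjamini–Hochberg adjusted)
can characterize any resulting set against a GMT pathway collection.

A synthetic-corpus generator (`zhengnet.synthetic`) plants gene mentions,
knowledge-base co-mentions and relation-cue verbs at configurable rates and
returns the ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from zhengnet import synthetic, ner, relations, network as net

cfg = synthetic.SyntheticConfig(n_genes=12, n_abstracts=100, seed=7)
dictionary, kb, corpus, truth, *_ = synthetic.gen_bundle(cfg)
annotated = ner.annotate_corpus(corpus, ner.GeneDictionary(dictionary))
bags = relations.generate_bags(annotated, kb)
model = relations.train_mil(bags, seed=7)
preds = relations.predict_relations(model, bags, threshold=0.5)
graph = net.build_network(preds)
print(net.rank_genes(graph, seed=7).head(5).to_string(index=False))
```

prints

```
 Id   Gene   Degree  Closeness  Betweenness      Hub      CMI  ZSW       GW
  1   JRN6 1.000000   1.000000     1.000000 0.919463 1.919463  1.0 2.919463
  2 KWCPZ7 1.000000   0.956522     0.770492 1.000000 1.805514  1.0 2.805514
  3 LNNNG6 1.000000   0.846154     0.852459 0.600869 1.608320  1.0 2.608320
  4 XZBFH5 1.000000   0.814815     0.377049 0.905580 1.368322  1.0 2.368322
  5   BXX5 0.666667   0.733333     0.213115 0.609883 0.803624  1.0 1.803624
```

All 66 co-mentioned pairs became bags, the 13 knowledge-base pairs were
recovered as predicted relations, and the ranking orders the 12 network
genes by GW: `JRN6` tops every centrality column except Hub, and since the
network decomposes into sub-networks tied on SW, every ZSW is 1 and GW is
CMI + 1. The same stages are exposed on the command line
(`zhengnet simulate | ner | relations | network | combine`).

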