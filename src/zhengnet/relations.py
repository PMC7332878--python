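"""Bag construction and sparse multi-instance relation extraction.

A *bag* is the unit of distant supervision: one bag per unordered gene
pair co-mentioned anywhere in the corpus, holding every evidence sentence
of that pair, flagged 1 when the pair is in the knowledge base and 0
otherwise.  Bags are deduplicated globally, so a pair co-mentioned in ten
abstracts still yields a single bag whose instances span all ten.

The classifier is a sparsity-regularized (L1) linear instance scorer with
log-mean-exp smooth-max pooling over instances: the bag logit is

    z(B) = log( mean_i exp(w . x_i + b) )

and the bag probability sigmoid(z).  Training minimizes bag-level logistic
loss with a proximal (soft-threshold) step for the L1 penalty; full-batch
gradient descent from a zero initialization makes it deterministic.  The
classifier sits behind a small interface so other bag classifiers can be
plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import FeatureMapMismatchError, ValidationError
from .io import GenePairKey, pair_key
from .ner import AnnotatedCorpus, tokenize
from .synthetic import CUE_VERBS

DEFAULT_CUE_LEXICON = frozenset(CUE_VERBS) | frozenset(
    {"interacts", "interaction", "activated", "inhibited", "bound"})


@dataclass(frozen=True)
class Instance:
    """One evidence sentence for a gene pair."""

    record_id: str
    sentence_index: int
    text: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]


@dataclass
class Bag:
    """All evidence for one unordered gene pair, with its distant label."""

    pair: GenePairKey
    instances: list[Instance]
    flag: int

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValidationError(f"bag {self.pair} has no instances")
        if self.flag not in (0, 1):
            raise ValidationError("bag flag must be 0 or 1")


@dataclass(frozen=True)
class RelationPrediction:
    pair: GenePairKey
    score: float
    label: int
    n_instances: int


def generate_bags(annotated: AnnotatedCorpus,
                  knowledge_base: Mapping[GenePairKey, float] | Iterable[GenePairKey],
                  ) -> list[Bag]:
    """Build one flagged bag per distinct co-mentioned gene pair.

    Sentence-level co-mentions are the instances; when a pair shares an
    abstract but never a sentence, the two mention sentences are joined
    into a single abstract-level fallback instance.  Flags record
    knowledge-base membership at construction time.
    """
    if not isinstance(annotated, AnnotatedCorpus):
        raise ValidationError("generate_bags requires an AnnotatedCorpus "
                              "(run ner.annotate_corpus first)")
    kb_pairs = set(knowledge_base)
    bags: dict[GenePairKey, Bag] = {}
    for rec in annotated.records:
        mentions = annotated.mentions.get(rec.record_id, [])
        sentences = annotated.sentences.get(rec.record_id, [])
        by_sentence: dict[int, list] = {}
        for m in mentions:
            by_sentence.setdefault(m.sentence_index, []).append(m)
        pairs_in_record: set[GenePairKey] = set()
        covered: set[GenePairKey] = set()
        # sentence-level instances
        for k, ms in sorted(by_sentence.items()):
            distinct = sorted({m.symbol for m in ms})
            for i in range(len(distinct)):
                for j in range(i + 1, len(distinct)):
                    pair = pair_key(distinct[i], distinct[j])
                    ma = next(m for m in ms if m.symbol == pair[0])
                    mb = next(m for m in ms if m.symbol == pair[1])
                    inst = Instance(rec.record_id, k, sentences[k],
                                    (ma.start, ma.end), (mb.start, mb.end))
                    _add_instance(bags, pair, inst, kb_pairs)
                    covered.add(pair)
        # abstract-level fallback for pairs never sharing a sentence
        record_genes = sorted({m.symbol for m in mentions})
        for i in range(len(record_genes)):
            for j in range(i + 1, len(record_genes)):
                pair = pair_key(record_genes[i], record_genes[j])
                if pair in covered:
                    continue
                ma = next(m for m in mentions if m.symbol == pair[0])
                mb = next(m for m in mentions if m.symbol == pair[1])
                sent_a = sentences[ma.sentence_index]
                sent_b = sentences[mb.sentence_index]
                joined = f"{sent_a} {sent_b}"
                inst = Instance(rec.record_id, ma.sentence_index, joined,
                                (ma.start, ma.end),
                                (len(sent_a) + 1 + mb.start,
                                 len(sent_a) + 1 + mb.end))
                _add_instance(bags, pair, inst, kb_pairs)
    return [bags[p] for p in sorted(bags)]


def _add_instance(bags: dict[GenePairKey, Bag], pair: GenePairKey,
                  inst: Instance, kb_pairs: set[GenePairKey]) -> None:
    if pair in bags:
        bags[pair].instances.append(inst)
    else:
        bags[pair] = Bag(pair, [inst], int(pair in kb_pairs))


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

_N_DISTANCE_BUCKETS = 4


def _distance_bucket(n_between: int) -> int:
    if n_between <= 2:
        return 0
    if n_between <= 5:
        return 1
    if n_between <= 10:
        return 2
    return 3


class BagFeaturizer:
    """Sparse per-instance features: windowed bag-of-words, distance, cues.

    The vocabulary indexes tokens between the two mentions plus a
    ``window``-token context on each side, fit on training bags only;
    unseen test tokens map to a reserved OOV feature.  Extra features:
    a one-hot token-distance bucket and a cue-lexicon presence bit.
    """

    def __init__(self, cue_lexicon: Iterable[str] = DEFAULT_CUE_LEXICON,
                 window: int = 3):
        self.cue_lexicon = frozenset(w.casefold() for w in cue_lexicon)
        self.window = window
        self.vocab: dict[str, int] | None = None

    # feature layout: [0]=OOV, [1..V]=vocab, then distance buckets, then cue
    @property
    def n_features(self) -> int:
        if self.vocab is None:
            raise FeatureMapMismatchError("featurizer not fitted")
        return 1 + len(self.vocab) + _N_DISTANCE_BUCKETS + 1

    def _context_tokens(self, inst: Instance) -> tuple[list[str], int]:
        toks = tokenize(inst.text)
        (a0, a1), (b0, b1) = sorted([inst.span_a, inst.span_b])
        idx_a = [i for i, t in enumerate(toks) if t.start >= a0 and t.end <= a1]
        idx_b = [i for i, t in enumerate(toks) if t.start >= b0 and t.end <= b1]
        if not idx_a or not idx_b:
            words = [t.text.casefold() for t in toks if t.text.isalnum()]
            return words, len(words)
        lo, hi = idx_a[-1] + 1, idx_b[0]
        between = toks[lo:hi]
        left = toks[max(0, idx_a[0] - self.window):idx_a[0]]
        right = toks[idx_b[-1] + 1:idx_b[-1] + 1 + self.window]
        words = [t.text.casefold() for t in (*left, *between, *right)
                 if any(c.isalnum() for c in t.text)]
        return words, len(between)

    def fit(self, bags: Sequence[Bag]) -> "BagFeaturizer":
        vocab: set[str] = set()
        for bag in bags:
            for inst in bag.instances:
                words, _ = self._context_tokens(inst)
                vocab.update(words)
        self.vocab = {w: i + 1 for i, w in enumerate(sorted(vocab))}
        return self

    def transform_bag(self, bag: Bag) -> sp.csr_matrix:
        """Feature matrix, one row per instance. Deterministic."""
        if self.vocab is None:
            raise FeatureMapMismatchError("featurizer not fitted")
        rows, cols, vals = [], [], []
        for r, inst in enumerate(bag.instances):
            words, n_between = self._context_tokens(inst)
            seen: set[int] = set()
            for w in words:
                seen.add(self.vocab.get(w, 0))
            for c in seen:
                rows.append(r)
                cols.append(c)
                vals.append(1.0)
            rows.append(r)
            cols.append(1 + len(self.vocab) + _distance_bucket(n_between))
            vals.append(1.0)
            if any(w in self.cue_lexicon for w in words):
                rows.append(r)
                cols.append(self.n_features - 1)
                vals.append(1.0)
        return sp.csr_matrix((vals, (rows, cols)),
                             shape=(len(bag.instances), self.n_features))

    @property
    def cue_feature_index(self) -> int:
        return self.n_features - 1


# ---------------------------------------------------------------------------
# Sparse MIL classifier
# ---------------------------------------------------------------------------

@dataclass
class SparseMILModel:
    """Trained L1 instance scorer with log-mean-exp bag pooling."""

    featurizer: BagFeaturizer
    weights: np.ndarray
    bias: float
    l1: float
    seed: int

    def bag_logit(self, bag: Bag) -> float:
        x = self.featurizer.transform_bag(bag)
        if x.shape[1] != self.weights.shape[0]:
            raise FeatureMapMismatchError(
                f"feature dimension {x.shape[1]} != model {self.weights.shape[0]}")
        s = x @ self.weights + self.bias
        m = float(np.max(s))
        return m + float(np.log(np.mean(np.exp(s - m))))

    def bag_score(self, bag: Bag) -> float:
        """Bag-level relation probability in [0, 1]."""
        return float(1.0 / (1.0 + np.exp(-self.bag_logit(bag))))


def train_mil(bags: Sequence[Bag], l1: float = 0.01, lr: float = 0.5,
              n_iter: int = 300, seed: int = 0,
              featurizer: BagFeaturizer | None = None) -> SparseMILModel:
    """Train the sparse MIL classifier on bag-level flags.

    Full-batch proximal gradient descent from zero weights; deterministic
    given the inputs (the seed is recorded for provenance and reserved for
    stochastic variants).  Requires at least one positive and one negative
    bag.
    """
    flags = np.array([b.flag for b in bags], dtype=float)
    if len(set(flags.tolist())) < 2:
        raise ValidationError("training requires both positive and negative bags")
    feat = featurizer or BagFeaturizer()
    if feat.vocab is None:
        feat.fit(bags)
    xs = [feat.transform_bag(b) for b in bags]
    dim = feat.n_features
    w = np.zeros(dim)
    b = 0.0
    n = len(bags)
    for _ in range(n_iter):
        grad_w = np.zeros(dim)
        grad_b = 0.0
        for x, y in zip(xs, flags):
            s = np.asarray(x @ w).ravel() + b
            m = s.max()
            e = np.exp(s - m)
            z = m + np.log(e.mean())
            p = 1.0 / (1.0 + np.exp(-z))
            soft = e / e.sum()  # d z / d s_i
            coef = (p - y)
            grad_w += coef * np.asarray((x.T @ soft)).ravel()
            grad_b += coef
        w -= lr * grad_w / n
        b -= lr * grad_b / n
        # proximal soft-threshold for the L1 penalty (bias unpenalized)
        thresh = lr * l1
        w = np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)
    return SparseMILModel(featurizer=feat, weights=w, bias=float(b),
                          l1=l1, seed=seed)


def predict_relations(model: SparseMILModel, bags: Sequence[Bag],
                      threshold: float = 0.5) -> list[RelationPrediction]:
    """Score every bag; label 1 iff score >= threshold; sort by score desc."""
    preds = [RelationPrediction(pair=b.pair, score=model.bag_score(b),
                                label=int(model.bag_score(b) >= threshold),
                                n_instances=len(b.instances))
             for b in bags]
    preds.sort(key=lambda p: (-p.score, p.pair))
    return preds


def split_bags(bags: Sequence[Bag], test_fraction: float, seed: int
               ) -> tuple[list[Bag], list[Bag]]:
    """Deterministic shuffled train/test split of bags."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bags))
    n_test = int(round(test_fraction * len(bags)))
    test_idx = set(order[:n_test].tolist())
    train = [b for i, b in enumerate(bags) if i not in test_idx]
    test = [b for i, b in enumerate(bags) if i in test_idx]
    return train, test


def write_predictions_tsv(preds: Sequence[RelationPrediction], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\tlabel\tn_instances\n")
        for p in preds:
            fh.write(f"{p.pair[0]}\t{p.pair[1]}\t{p.score:.6f}\t{p.label}\t"
                     f"{p.n_instances}\n")
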