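"""Synthetic corpora, dictionaries, knowledge bases and symptom structures.

Every downstream stage of the pipeline — dictionary NER, bag construction,
multi-instance relation learning, network scoring, symptom-combination
intersection — is testable against these generators with no external
download.  The generators plant a known signal and return a ground-truth
record so that recovery can be measured:

* gene mentions are planted in templated English sentences
  (subject-verb-object with gene slots plus filler sentences);
* knowledge-base gene pairs co-occur in an abstract with probability
  ``comention_rate_kb``, all other pairs with ``comention_rate_bg``;
* co-mention sentences of knowledge-base pairs carry a relation-cue verb
  ("activates", "inhibits", ...) with probability ``cue_rate``, other
  co-mentions use neutral phrasing;
* symptom-gene hit counts are Poisson with a fixed zero-inflated fraction
  of symptoms mapped to no gene at all, mirroring real keyword searches
  where some symptoms return nothing.

The filler vocabulary is disjoint from every generated gene surface, so
dictionary matching on these corpora has precision 1 by construction.

Randomness: each generator draws from its own stream derived from the
master seed by stable sub-seeding (seed + CRC32 of the stream name), so
adding one generator never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .io import AbstractRecord, GeneEntry, GenePairKey, pair_key

# Relation-cue verbs; the relation-extraction featurizer's default lexicon
# covers exactly these forms.
CUE_VERBS = ("activates", "inhibits", "binds", "phosphorylates",
             "regulates", "suppresses", "induces", "stabilizes")

# Neutral co-mention templates: the two genes share a sentence but no cue.
_NEUTRAL_TEMPLATES = (
    "{a} and {b} were measured in the cohort",
    "{a} levels were compared with {b} levels",
    "expression of {a} and of {b} was profiled",
    "{a} together with {b} appeared in the panel",
)

_SINGLE_TEMPLATES = (
    "{a} expression was quantified in all samples",
    "serum {a} was assayed at baseline",
    "{a} transcripts were profiled across tissues",
)

# Filler vocabulary: common words only, never overlapping gene surfaces.
_FILLER_WORDS = (
    "patients were recruited from two clinical centers",
    "baseline characteristics were balanced between groups",
    "samples were processed under a standard protocol",
    "statistical analysis used mixed effects models",
    "the follow up period lasted twelve months",
    "outcomes were assessed by blinded reviewers",
    "tissue sections were stained and scored",
    "the cohort included both early and late cases",
)

_SYMPTOM_TERMS = (
    "dizziness", "fatigue", "palpitation", "chest pain", "headache",
    "constipation", "xerostomia", "irritability", "hemiplegia", "sweating",
    "insomnia", "ecchymoses", "lassitude", "glossitis", "sputum",
    "numbness", "anemia", "thirst", "vertigo", "dyspnea",
)

_CONSONANTS = np.array(list("BCDFGHJKLMNPQRSTVWXZ"))
_LETTERS = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent RNG stream derived from a master seed and a stream name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stream.encode())]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults are the standard evaluation conditions used throughout the
    test-suite: 20 genes, 400 abstracts, a knowledge base covering 15% of
    gene pairs, knowledge-base pairs co-mentioned fifteen times more often
    than background pairs, and a strong (0.9) cue rate on true-relation
    sentences.
    """

    n_genes: int = 20
    n_abstracts: int = 400
    kb_density: float = 0.15
    comention_rate_kb: float = 0.3
    comention_rate_bg: float = 0.02
    cue_rate: float = 0.9
    n_symptoms: int = 12
    hits_lambda: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise InvalidParameterError("n_genes must be >= 2")
        if self.n_abstracts < 1:
            raise InvalidParameterError("n_abstracts must be >= 1")
        if self.n_symptoms < 1:
            raise InvalidParameterError("n_symptoms must be >= 1")
        if self.hits_lambda < 0:
            raise InvalidParameterError("hits_lambda must be >= 0")
        for name in ("kb_density", "comention_rate_kb", "comention_rate_bg",
                     "cue_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0,1]")
        if (self.comention_rate_kb < self.comention_rate_bg
                or (self.comention_rate_kb == self.comention_rate_bg
                    and self.comention_rate_kb > 0)):
            raise InvalidParameterError(
                "comention_rate_kb must exceed comention_rate_bg "
                "(planted signal must be recoverable)")


@dataclass(frozen=True)
class PlantedComention:
    record_id: str
    sentence_index: int
    pair: GenePairKey
    in_kb: bool
    has_cue: bool


@dataclass(frozen=True)
class PlantedMention:
    record_id: str
    sentence_index: int
    symbol: str
    surface: str


@dataclass
class CorpusTruth:
    """Ground-truth record of everything the generator planted."""

    comentions: list[PlantedComention] = field(default_factory=list)
    mentions: list[PlantedMention] = field(default_factory=list)

    @property
    def kb_pairs_planted(self) -> set[GenePairKey]:
        return {c.pair for c in self.comentions if c.in_kb}

    @property
    def comentioned_pairs(self) -> set[GenePairKey]:
        return {c.pair for c in self.comentions}


def gen_gene_dictionary(n_genes: int, seed: int) -> list[GeneEntry]:
    """Generate ``n_genes`` unique gene entries with 0-2 synonyms each.

    Symbols are consonant-heavy 3-5-letter uppercase strings with a digit
    suffix (e.g. ``KTRB2``), guaranteed unique and disjoint from the filler
    vocabulary; synonyms are derived forms that map back to exactly one
    symbol.  Deterministic for a fixed seed.
    """
    if n_genes < 2:
        raise InvalidParameterError("n_genes must be >= 2")
    rng = stream_rng(seed, "gene_dictionary")
    symbols: list[str] = []
    seen: set[str] = set()
    while len(symbols) < n_genes:
        length = int(rng.integers(3, 6))
        base = "".join(rng.choice(_CONSONANTS, size=length))
        sym = f"{base}{int(rng.integers(1, 10))}"
        if sym.casefold() in seen:
            continue
        seen.add(sym.casefold())
        symbols.append(sym)
    entries: list[GeneEntry] = []
    for sym in symbols:
        n_syn = int(rng.integers(0, 3))
        syns = []
        for k in range(n_syn):
            # hyphenated and suffixed variants, e.g. KTRB-2, KTRB2P
            cand = f"{sym[:-1]}-{sym[-1]}" if k == 0 else f"{sym}P"
            if cand.casefold() not in seen:
                seen.add(cand.casefold())
                syns.append(cand)
        entries.append(GeneEntry(sym, tuple(syns)))
    return entries


def gen_knowledge_base(dictionary: Sequence[GeneEntry], kb_density: float,
                       seed: int) -> dict[GenePairKey, float]:
    """Sample unordered gene pairs independently with probability kb_density.

    Expected size is ``kb_density * C(n_genes, 2)``; no self-pairs, no
    duplicates.  Each pair carries a confidence-like score in (0.4, 0.99).
    """
    if not dictionary:
        raise InvalidParameterError("dictionary must be nonempty")
    if not 0.0 <= kb_density <= 1.0:
        raise InvalidParameterError(f"kb_density={kb_density} outside [0,1]")
    rng = stream_rng(seed, "knowledge_base")
    kb: dict[GenePairKey, float] = {}
    for a, b in combinations(sorted(e.symbol for e in dictionary), 2):
        if rng.random() < kb_density:
            kb[pair_key(a, b)] = round(0.4 + 0.59 * rng.random(), 3)
    return kb


def gen_abstract_corpus(
    dictionary: Sequence[GeneEntry],
    knowledge_base: Mapping[GenePairKey, float],
    config: SyntheticConfig,
) -> tuple[list[AbstractRecord], CorpusTruth]:
    """Generate a corpus of templated abstracts with planted gene mentions.

    Per abstract, every knowledge-base pair co-occurs in one sentence with
    probability ``comention_rate_kb`` and every other pair with
    ``comention_rate_bg``; knowledge-base co-mention sentences carry a cue
    verb with probability ``cue_rate``.  Abstracts with no co-mention get
    one single-gene sentence, so a zero-rate corpus never co-mentions two
    distinct genes.  Returns the corpus and the planted-truth record.
    """
    if not dictionary:
        raise InvalidParameterError("dictionary must be nonempty")
    rng = stream_rng(config.seed, "abstract_corpus")
    symbols = sorted(e.symbol for e in dictionary)
    surfaces = {e.symbol: (e.symbol, *e.synonyms) for e in dictionary}
    all_pairs = [pair_key(a, b) for a, b in combinations(symbols, 2)]
    records: list[AbstractRecord] = []
    truth = CorpusTruth()

    for i in range(config.n_abstracts):
        rid = f"SYN{i:06d}"
        planted: list[tuple[GenePairKey, bool, bool]] = []
        for pair in all_pairs:
            in_kb = pair in knowledge_base
            rate = config.comention_rate_kb if in_kb else config.comention_rate_bg
            if rng.random() < rate:
                has_cue = bool(in_kb and rng.random() < config.cue_rate)
                planted.append((pair, in_kb, has_cue))

        sentences: list[tuple[str, list[tuple[str, str]],
                              tuple[GenePairKey, bool, bool] | None]] = []
        for pair, in_kb, has_cue in planted:
            surf_a = str(rng.choice(surfaces[pair[0]]))
            surf_b = str(rng.choice(surfaces[pair[1]]))
            if has_cue:
                verb = str(rng.choice(CUE_VERBS))
                text = f"{surf_a} {verb} {surf_b} in this model"
            else:
                text = str(rng.choice(_NEUTRAL_TEMPLATES)).format(a=surf_a, b=surf_b)
            sentences.append((text, [(pair[0], surf_a), (pair[1], surf_b)],
                              (pair, in_kb, has_cue)))
        if not planted:
            sym = str(rng.choice(symbols))
            surf = str(rng.choice(surfaces[sym]))
            text = str(rng.choice(_SINGLE_TEMPLATES)).format(a=surf)
            sentences.append((text, [(sym, surf)], None))

        n_filler = int(rng.integers(2, 5))
        for _ in range(n_filler):
            sentences.append((str(rng.choice(_FILLER_WORDS)), [], None))
        rng.shuffle(sentences)

        body_parts: list[str] = []
        for k, (text, mention_list, comention) in enumerate(sentences):
            body_parts.append(text.capitalize() if not mention_list else text)
            for symbol, surface in mention_list:
                truth.mentions.append(PlantedMention(rid, k, symbol, surface))
            if comention is not None:
                pair, in_kb, has_cue = comention
                truth.comentions.append(
                    PlantedComention(rid, k, pair, in_kb, has_cue))
        abstract = ". ".join(body_parts) + "."
        title = f"Synthetic study {i} of the generated cohort"
        records.append(AbstractRecord(rid, title, abstract))
    return records, truth


# Fraction of symptoms forced to map to zero genes (zero inflation),
# reproducing the pruning path real keyword searches trigger when a symptom
# returns no literature hits.
ZERO_SYMPTOM_FRACTION = 0.2


def gen_symptom_structure(
    dictionary: Sequence[GeneEntry], n_symptoms: int, hits_lambda: float,
    seed: int,
) -> tuple[list[str], dict[str, dict[str, int]], dict[str, list[str]]]:
    """Generate symptom terms, Poisson symptom-gene hit counts and a term map.

    A fixed 20% of symptoms (at least one when ``n_symptoms >= 5``) are
    forced to all-zero rows; the remaining cells are independent
    Poisson(``hits_lambda``).  The returned term map covers every symptom
    with a source-language alias ``tcm:<term>``.
    """
    if n_symptoms < 1:
        raise InvalidParameterError("n_symptoms must be >= 1")
    if hits_lambda < 0:
        raise InvalidParameterError("hits_lambda must be >= 0")
    rng = stream_rng(seed, "symptom_structure")
    terms = list(_SYMPTOM_TERMS[:n_symptoms])
    for j in range(len(terms), n_symptoms):
        terms.append(f"symptom {j}")
    n_zero = int(np.floor(ZERO_SYMPTOM_FRACTION * n_symptoms))
    zero_idx = set(rng.choice(n_symptoms, size=n_zero, replace=False).tolist())
    symbols = sorted(e.symbol for e in dictionary)
    hits: dict[str, dict[str, int]] = {}
    for s_idx, term in enumerate(terms):
        if s_idx in zero_idx:
            hits[term] = {g: 0 for g in symbols}
        else:
            counts = rng.poisson(hits_lambda, size=len(symbols))
            hits[term] = {g: int(c) for g, c in zip(symbols, counts)}
    term_map = {f"tcm:{t}": [t] for t in terms}
    return terms, hits, term_map


def gen_bundle(config: SyntheticConfig):
    """Generate the full synthetic bundle for one configuration.

    Returns (dictionary, knowledge_base, corpus, truth, symptoms, hits,
    term_map), all driven by independent streams of ``config.seed``.
    """
    dictionary = gen_gene_dictionary(config.n_genes, config.seed)
    kb = gen_knowledge_base(dictionary, config.kb_density, config.seed)
    corpus, truth = gen_abstract_corpus(dictionary, kb, config)
    symptoms, hits, term_map = gen_symptom_structure(
        dictionary, config.n_symptoms, config.hits_lambda, config.seed)
    return dictionary, kb, corpus, truth, symptoms, hits, term_map
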